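"""Overlap statistics, classification thresholds, ChIP and localization."""

import numpy as np
import pandas as pd
import pytest

from rbpatlas.annotation import Annotation, GeneModel, Transcript
from rbpatlas.integrate import (
    chip_at_eclip,
    chip_kd_dependence,
    classify_localization,
    de_classify,
    expression_overlap,
    expression_overlap_batch,
    fisher_or_yates,
    gene_body_mask,
    jaccard_index,
    jaccard_matrix,
    ks_by_enrichment,
    localization_association,
    miso_tandem_filter,
    promoter_mask,
    spliced_unspliced_counts,
    splicing_classify,
)
from rbpatlas.reads import ReadRecord


class TestClassification:
    @pytest.mark.parametrize(
        "lfc,expected", [(2.0, "strong"), (-2.5, "strong"), (1.5, "moderate"),
                         (1.0, "weak"), (0.3, "weak")]
    )
    def test_de_classes(self, lfc, expected):
        assert de_classify(lfc) == expected

    @pytest.mark.parametrize(
        "dpsi,expected", [(0.30, "strong"), (-0.4, "strong"), (0.20, "moderate"),
                          (0.15, "moderate"), (0.06, "weak"), (0.149, "weak")]
    )
    def test_splicing_classes(self, dpsi, expected):
        assert splicing_classify(dpsi) == expected

    def test_splicing_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            splicing_classify(0.05)


class TestMisoFilter:
    def test_all_strong_significant(self):
        comps = [(10, 0.01)] * 4
        assert miso_tandem_filter(comps, [(10, 0.01), (8, 0.02)])

    def test_weak_bayes_factor_fails(self):
        comps = [(10, 0.01)] * 3 + [(4, 0.01)]
        assert not miso_tandem_filter(comps, [(10, 0.01), (10, 0.01)])

    def test_weak_grouping_p_fails(self):
        comps = [(10, 0.01)] * 4
        assert not miso_tandem_filter(comps, [(10, 0.01), (10, 0.2)])

    def test_negative_bayes_factor_counts_by_magnitude(self):
        comps = [(-10, 0.01)] * 4
        assert miso_tandem_filter(comps, [(-6, 0.01), (7, 0.01)])

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError):
            miso_tandem_filter([(10, 0.01)] * 3, [(10, 0.01)] * 2)


class TestExpressionOverlap:
    def test_independent_table_near_one(self):
        p, method = fisher_or_yates(np.array([[25, 25], [25, 25]]))
        assert p > 0.9

    def test_fisher_branch_matches_oracle(self):
        from tests_oracles import fisher_two_sided_oracle

        p, method = fisher_or_yates(np.array([[30, 2], [3, 30]]))
        assert method == "fisher"  # small cells force the exact test
        assert abs(p - fisher_two_sided_oracle(30, 2, 3, 30)) < 1e-9

    def test_yates_branch_matches_closed_form(self):
        table = np.array([[30, 10], [10, 30]])
        p, method = fisher_or_yates(table)
        assert method == "yates"
        n = table.sum()
        a, b, c, d = table.ravel()
        chi = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        from scipy import stats

        assert p == pytest.approx(stats.chi2.sf(chi, 1), rel=1e-12)

    def test_small_de_set_skipped(self):
        background = {f"g{i}" for i in range(100)}
        res = expression_overlap({"g1", "g2"}, {f"g{i}" for i in range(10)}, background)
        assert res is None

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            expression_overlap({"a"}, {"b"}, set())

    def test_bonferroni_over_executed_family(self):
        background = {f"g{i}" for i in range(200)}
        de = {f"g{i}" for i in range(40)}
        bound = {f"g{i}" for i in range(20, 60)}
        comparisons = {
            "up": expression_overlap(bound, de, background),
            "down": expression_overlap(bound, set(list(background)[:15]), background),
            "skipped": None,
        }
        comparisons["skipped"] = expression_overlap(bound, set(), background)
        batch = expression_overlap_batch(comparisons)
        assert len(batch) == 2  # skipped comparisons excluded from the family
        assert (batch["p_bonferroni"] >= batch["p"]).all()


class TestKs:
    def test_identical_samples_p_one(self):
        fc = pd.Series(np.arange(10, dtype=float).tolist() * 2)
        cats = pd.Series(["a"] * 10 + ["b"] * 10)
        assert ks_by_enrichment(fc, cats)[("a", "b")] == pytest.approx(1.0)

    def test_shift_detected(self, rng):
        x = rng.normal(0, 1, 500)
        fc = pd.Series(np.concatenate([x, x + 0.5]))
        cats = pd.Series(["low"] * 500 + ["high"] * 500)
        assert ks_by_enrichment(fc, cats)[("low", "high")] < 1e-5

    def test_degenerate_category_skipped(self):
        fc = pd.Series([1.0, 2.0, 3.0])
        cats = pd.Series(["a", "a", "b"])
        assert ks_by_enrichment(fc, cats) == {}


class TestJaccard:
    def test_identity_disjoint_and_interval_arithmetic(self):
        assert jaccard_index([(0, 100)], [(0, 100)], 1000) == 1.0
        assert jaccard_index([(0, 100)], [(200, 300)], 1000) == 0.0
        assert jaccard_index([(0, 100)], [(50, 150)], 1000) == pytest.approx(1 / 3)

    def test_empty_set_zero_by_convention(self):
        assert jaccard_index([], [(0, 10)], 100) == 0.0

    def test_matrix_symmetry_and_range(self, annotation, rng):
        sets = {
            name: [(int(s), int(s) + 100) for s in rng.integers(0, annotation.length - 100, 30)]
            for name in ("A", "B", "C")
        }
        mats = jaccard_matrix(sets, annotation)
        for mat in mats.values():
            assert np.allclose(mat, mat.T)
            assert ((mat >= 0) & (mat <= 1)).all().all()
            assert np.allclose(np.diag(mat), 1.0) or (np.diag(mat) == 0).any()


class TestChipAtEclip:
    def peaks(self, starts, width=50):
        return pd.DataFrame(
            [{"chrom": "chrS", "start": s, "end": s + width, "strand": "+"}
             for s in starts]
        )

    def test_uniform_signal_null_calibrated(self, rng):
        # the one-sided p is uniform under the null: check the median over
        # replicates rather than a single draw
        ps = []
        for _ in range(11):
            signal = 1.0 + rng.random(100000)  # flat in expectation
            res = chip_at_eclip(signal, self.peaks(rng.integers(1000, 90000, 100)))
            ps.append(res["p"])
            assert not res["significant"]
        assert 0.15 < np.median(ps) < 0.85

    def test_doubled_signal_detected(self, rng):
        signal = np.ones(300000) + rng.random(300000) * 0.1
        starts = rng.integers(1000, 290000, 200)
        for s in starts:
            signal[s : s + 50] *= 2
        res = chip_at_eclip(signal, self.peaks(starts))
        assert res["p"] < 0.001 and res["significant"]

    def test_all_zero_track_not_applicable(self):
        res = chip_at_eclip(np.zeros(10000), self.peaks([100, 500]))
        assert np.isnan(res["p"]) and not res["significant"]

    def test_flank_truncation_flagged(self):
        signal = np.ones(2000)
        res = chip_at_eclip(signal, self.peaks([10, 1900]))
        assert res["n_truncated"] == 2

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            chip_at_eclip(-np.ones(100), self.peaks([10]))


class TestChipKdDependence:
    def gene_table(self, rng, n, or_target=1.0, p_de=0.2, p_bound=0.4):
        tpm = rng.lognormal(2, 1, n)
        bound = rng.random(n) < p_bound
        # convert target odds ratio to DE probability among bound genes
        odds0 = p_de / (1 - p_de)
        p_de_bound = or_target * odds0 / (1 + or_target * odds0)
        de = np.where(bound, rng.random(n) < p_de_bound, rng.random(n) < p_de)
        return pd.DataFrame({"tpm": tpm, "tss_bound": bound, "de": de})

    def test_balanced_table_or_one(self):
        genes = pd.DataFrame(
            {
                "tpm": np.ones(400),
                "tss_bound": [True, False] * 200,
                "de": [True, True, False, False] * 100,
            }
        )
        res = chip_kd_dependence(genes, n_rounds=20, seed=0)
        assert np.nanmedian(res["odds_ratios"]) == pytest.approx(1.0, abs=0.2)
        assert not res["verdict"]

    def test_planted_dependence_detected(self, rng):
        genes = self.gene_table(rng, 800, or_target=4.0)
        res = chip_kd_dependence(genes, n_rounds=50, seed=1)
        assert res["verdict"]

    def test_matching_infeasible_not_applicable(self):
        genes = pd.DataFrame(
            {"tpm": [1.0] * 5, "tss_bound": [True] * 5, "de": [False] * 5}
        )
        assert chip_kd_dependence(genes)["verdict"] is None


class TestLocalization:
    def test_ratio_classification(self):
        assert classify_localization(2.0) == "nuclear"
        assert classify_localization(0.5) == "cytoplasmic"
        assert classify_localization(1.0) == "neither"
        with pytest.raises(ValueError):
            classify_localization(0.0)

    def test_planted_shift_detected(self, rng):
        rbps = [f"R{i}" for i in range(40)]
        labeled = rng.permutation([True] * 20 + [False] * 20)
        info = rng.normal(0, 1, 40) + 2.0 * labeled
        information = pd.DataFrame({"rRNA": info}, index=rbps)
        labels = pd.DataFrame({"nucleolus": labeled}, index=rbps)
        res = localization_association(information, labels)
        assert res.loc[0, "p"] < 0.01

    def test_identical_values_near_half(self):
        rbps = [f"R{i}" for i in range(20)]
        information = pd.DataFrame({"mRNA": np.arange(20.0)}, index=rbps)
        labels = pd.DataFrame({"lab": [True, False] * 10}, index=rbps)
        res = localization_association(information, labels)
        assert 0.2 < res.loc[0, "p"] < 0.8

    def test_one_sided_split_skipped(self):
        rbps = ["R1", "R2", "R3"]
        information = pd.DataFrame({"mRNA": [1.0, 2.0, 3.0]}, index=rbps)
        labels = pd.DataFrame({"lab": [True, True, True]}, index=rbps)
        assert len(localization_association(information, labels)) == 0


def two_exon_annotation():
    g = GeneModel(
        "G1", "protein_coding", "chrS", "+",
        [Transcript("G1.t1", [(100, 300), (500, 700)], cds=(150, 650))],
        tpm={"cellA": 1.0},
    )
    return Annotation("chrS", 1000, [g])


class TestSplicedUnspliced:
    def test_junction_spanning_read_with_overhangs(self):
        ann = two_exon_annotation()
        read = ReadRecord("r1", "ACGTACGTAC", 288, 515,
                          blocks=((288, 300), (500, 515)))
        assert spliced_unspliced_counts([read], ann) == (1, 0)

    def test_nine_nt_overhang_is_neither(self):
        ann = two_exon_annotation()
        read = ReadRecord("r1", "ACGTACGTAC", 291, 515,
                          blocks=((291, 300), (500, 515)))
        assert spliced_unspliced_counts([read], ann) == (0, 0)

    def test_exon_intron_boundary_read_is_unspliced(self):
        ann = two_exon_annotation()
        read = ReadRecord("r1", "ACGTACGTAC", 285, 315)
        assert spliced_unspliced_counts([read], ann) == (0, 1)

    def test_short_read_never_classified(self):
        ann = two_exon_annotation()
        read = ReadRecord("r1", "ACGTACGTAC", 295, 310)
        assert spliced_unspliced_counts([read], ann) == (0, 0)

    def test_classification_mutually_exclusive(self):
        ann = two_exon_annotation()
        spliced = ReadRecord("r1", "A" * 10, 285, 520, blocks=((285, 300), (500, 520)))
        s, u = spliced_unspliced_counts([spliced], ann)
        assert (s, u) == (1, 0)


class TestMasks:
    def test_gene_body_excludes_tss_tts_windows(self):
        ann = two_exon_annotation()
        gb = gene_body_mask(ann)
        prom = promoter_mask(ann)
        assert not gb[100:600].all()  # TSS window carved out
        assert prom[100]
        assert not (gb & prom).any()
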