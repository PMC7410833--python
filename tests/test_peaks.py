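"""Peak merging, blacklist, priority annotation, preservation, saturation."""

import numpy as np
import pandas as pd
import pytest

from rbpatlas.annotation import (
    Annotation,
    CROSS_GENE_PRIORITY,
    GeneModel,
    INTERGENIC,
    Transcript,
    WITHIN_GENE_PRIORITY,
    transcript_region_intervals,
)
from rbpatlas.peaks import (
    annotate_peak,
    annotate_peaks,
    base_coverage_by_region,
    categorize_expression,
    cross_cell_preservation,
    interval_fold_enrichment,
    region_fraction_vector,
    remove_blacklist,
    reproducible_peaks,
    saturation_curve,
)
from rbpatlas.simulate import BindingTruth, coverage_from_records, simulate_eclip


def peak_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "l2fc", "nlp"])


class TestReproduciblePeaks:
    def test_geometric_mean_merging_fails_fold_filter(self):
        rep1 = peak_df([("chrS", 100, 200, "+", 4.0, 6.0)])
        rep2 = peak_df([("chrS", 120, 210, "+", 2.0, 6.0)])
        merged = reproducible_peaks(rep1, rep2)
        # sqrt(4*2) = 2.83 < 3 = log2(8): filtered out
        assert len(merged) == 0

    def test_identical_strong_replicates_all_pass(self):
        rows = [("chrS", i * 1000, i * 1000 + 100, "+", 4.0, 5.0) for i in range(20)]
        rep = peak_df(rows)
        merged = reproducible_peaks(rep, rep.copy())
        assert len(merged) == 20
        assert np.allclose(merged["l2fc"], 4.0)

    def test_empty_replicate_gives_empty_output(self):
        rep = peak_df([("chrS", 0, 100, "+", 5.0, 5.0)])
        assert len(reproducible_peaks(rep, peak_df([]))) == 0
        assert len(reproducible_peaks(peak_df([]), rep)) == 0

    def test_injectable_scorer_is_used(self):
        rep = peak_df([("chrS", 0, 100, "+", 5.0, 5.0)])
        reject_all = lambda merged: np.ones(len(merged))
        assert len(reproducible_peaks(rep, rep.copy(), scorer=reject_all)) == 0

    def test_strand_mismatch_never_merges(self):
        rep1 = peak_df([("chrS", 0, 100, "+", 5.0, 5.0)])
        rep2 = peak_df([("chrS", 0, 100, "-", 5.0, 5.0)])
        assert len(reproducible_peaks(rep1, rep2)) == 0


class TestBlacklist:
    def test_one_nt_overlap_removes(self):
        peaks = peak_df([("chrS", 100, 200, "+", 5.0, 5.0)])
        assert len(remove_blacklist(peaks, [(199, 300)])) == 0

    def test_half_open_boundary_keeps(self):
        peaks = peak_df([("chrS", 100, 200, "+", 5.0, 5.0)])
        assert len(remove_blacklist(peaks, [(200, 300)])) == 1

    def test_empty_blacklist_is_identity(self):
        peaks = peak_df([("chrS", 100, 200, "+", 5.0, 5.0)])
        pd.testing.assert_frame_equal(remove_blacklist(peaks, []), peaks)

    def test_anti_monotone_in_blacklist_size(self, rng):
        peaks = peak_df(
            [("chrS", int(s), int(s) + 50, "+", 5.0, 5.0)
             for s in rng.integers(0, 10000, 50)]
        )
        bl = [(int(s), int(s) + 100) for s in rng.integers(0, 10000, 20)]
        prev = len(peaks)
        for k in range(len(bl) + 1):
            n = len(remove_blacklist(peaks, bl[:k]))
            assert n <= prev
            prev = n


def conflict_annotation():
    """A compact annotation instantiating many pairwise label conflicts:
    overlapping genes, a miRNA inside an intron, a tRNA over a 3'UTR, and
    two isoforms whose CDS/3'UTR boundaries disagree."""
    coding = GeneModel(
        "GC", "protein_coding", "chrS", "+",
        [
            Transcript("GC.t1", [(1000, 1400), (3800, 4200), (6000, 6600)],
                       cds=(1200, 6300)),
            Transcript("GC.t2", [(1000, 1400), (6000, 6600)], cds=(1200, 6100)),
        ],
        tpm={"cellA": 10.0},
    )
    mirna = GeneModel(
        "GM", "miRNA", "chrS", "+",
        [Transcript("GM.t1", [(2000, 2090)])], tpm={"cellA": 1.0},
    )
    trna = GeneModel(
        "GT", "tRNA", "chrS", "+",
        [Transcript("GT.t1", [(6350, 6430)])], tpm={"cellA": 1.0},
    )
    noncoding = GeneModel(
        "GN", "noncoding", "chrS", "+",
        [Transcript("GN.t1", [(4100, 4500), (5000, 5400)])], tpm={"cellA": 1.0},
    )
    return Annotation("chrS", 8000, [coding, mirna, trna, noncoding])


def oracle_label(annotation, start, end, strand):
    """Naive rule-table oracle: exhaustive scan of every isoform interval."""
    per_gene = {}
    for g in annotation.genes:
        if g.strand != strand:
            continue
        labs = set()
        for t in g.transcripts:
            for s, e, lab in transcript_region_intervals(g, t):
                s, e = max(0, s), min(e, annotation.length)
                if s < end and e > start:
                    labs.add(lab)
        if labs:
            per_gene[g.gene_id] = labs
    if not per_gene:
        return INTERGENIC
    winners = {
        gid: sorted(labs, key=WITHIN_GENE_PRIORITY.index)[0]
        for gid, labs in per_gene.items()
    }
    best = sorted(
        winners.items(), key=lambda kv: (CROSS_GENE_PRIORITY.index(kv[1]), kv[0])
    )
    return best[0][1]


class TestAnnotatePeak:
    def test_cds_beats_3utr_within_one_gene(self):
        ann = conflict_annotation()
        # [6000, 6300) is CDS in isoform t1 but 3'UTR in isoform t2
        label, gene = annotate_peak(ann, 6150, 6250, "+")
        assert label == "CDS" and gene == "GC"

    def test_mirna_beats_cds_across_genes(self):
        ann = conflict_annotation()
        # peak over the miRNA (gene GM) while inside GC's intron
        label, gene = annotate_peak(ann, 2000, 2060, "+")
        assert label == "miRNA" and gene == "GM"

    def test_trna_beats_3utr_across_genes(self):
        ann = conflict_annotation()
        label, gene = annotate_peak(ann, 6360, 6420, "+")
        assert label == "tRNA" and gene == "GT"

    def test_400nt_into_intron_is_proximal(self):
        ann = conflict_annotation()
        # GC.t1 intron 2 runs [4200, 6000); ~400 nt in, outside every splice
        # site window but within 500 of the donor site
        label, _ = annotate_peak(ann, 4605, 4615, "+")
        assert label == "proximal intron"

    def test_intergenic_fallback(self):
        ann = conflict_annotation()
        assert annotate_peak(ann, 7500, 7600, "+")[0] == INTERGENIC
        assert annotate_peak(ann, 1200, 1300, "-")[0] == INTERGENIC

    def test_agrees_with_rule_table_oracle_everywhere(self):
        ann = conflict_annotation()
        observed = set()
        for width in (10, 80, 400):
            for start in range(0, ann.length - width, 37):
                label, _ = annotate_peak(ann, start, start + width, "+")
                assert label == oracle_label(ann, start, start + width, "+")
                observed.add(label)
        # the scan instantiated most of the vocabulary
        assert {"tRNA", "miRNA", "miRNA-proximal", "CDS", "3'UTR", "5'UTR",
                "5'ss", "3'ss", "proximal intron", "distal intron",
                "noncoding exonic"} <= observed

    def test_agrees_with_oracle_on_generated_annotation(self, annotation, rng):
        for _ in range(300):
            start = int(rng.integers(0, annotation.length - 200))
            width = int(rng.integers(5, 200))
            strand = "+" if rng.random() < 0.5 else "-"
            assert (
                annotate_peak(annotation, start, start + width, strand)[0]
                == oracle_label(annotation, start, start + width, strand)
            )


class TestRegionFractions:
    def test_fraction_vector_counts(self):
        peaks = pd.DataFrame({"label": ["CDS", "CDS", "CDS", "3'UTR"]})
        vec = region_fraction_vector(peaks)
        assert vec["CDS"] == pytest.approx(0.75)
        assert vec["3'UTR"] == pytest.approx(0.25)
        assert vec.sum() == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            region_fraction_vector(pd.DataFrame({"label": []}))


class TestExpressionCategories:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10, 10, "unchanged"),
            (10, 9, "unchanged"),          # 1.11-fold
            (10, 6, "weak"),               # 1.67-fold
            (10, 3, "moderate"),           # 3.3-fold
            (10, 1.5, "strong"),           # 6.7-fold
            (10, 0.05, "cell-type-specific"),
            (0.05, 10, "cell-type-specific"),
            (0.5, 0.5, "other"),
            (10, 0.5, "other"),            # low side between 0.1 and 1
        ],
    )
    def test_category_rules(self, a, b, expected):
        assert categorize_expression(a, b) == expected


class TestCrossCellPreservation:
    def test_identity_cell_preserves_enrichment_exactly(self, annotation):
        truth = BindingTruth(
            enriched_elements=[(g.start + 200, g.start + 400, 8.0)
                               for g in annotation.genes[:3]]
        )
        r1, _, inp = simulate_eclip(annotation, truth, 20000, 0.0, seed=8)
        ip_cov, ip_n = coverage_from_records(r1, annotation.length, annotation.chrom)
        in_cov, in_n = coverage_from_records(inp, annotation.length, annotation.chrom)
        peaks = pd.DataFrame(
            [
                {"chrom": "chrS", "start": g.start + 200, "end": g.start + 400,
                 "strand": g.strand, "gene_id": g.gene_id}
                for g in annotation.genes[:6]
            ]
        )
        expr = pd.DataFrame(
            {"tpm_a": [g.tpm["cellA"] for g in annotation.genes],
             "tpm_b": [g.tpm["cellA"] for g in annotation.genes]},
            index=[g.gene_id for g in annotation.genes],
        )
        per_peak, summary, _ = cross_cell_preservation(
            peaks, ip_cov, in_cov, ip_n, in_n, expr
        )
        fold_a = [
            interval_fold_enrichment(ip_cov, in_cov, ip_n, in_n, r.start, r.end)
            for r in peaks.itertuples()
        ]
        assert np.allclose(per_peak["fold_b"], fold_a, equal_nan=True)
        assert ((per_peak["fold_b"] >= 4) == (np.array(fold_a) >= 4)).all()

    def test_missing_expression_becomes_other(self):
        peaks = pd.DataFrame(
            [{"chrom": "chrS", "start": 0, "end": 10, "strand": "+",
              "gene_id": "UNKNOWN"}]
        )
        cov = np.ones(100)
        per_peak, _, _ = cross_cell_preservation(
            peaks, cov, cov, 100, 100, pd.DataFrame(columns=["tpm_a", "tpm_b"])
        )
        assert per_peak["category"].iloc[0] == "other"


class TestSaturation:
    def test_single_set_curve(self):
        res = saturation_curve([{"a", "b", "c"}], n_shuffles=5, seed=0)
        assert res["curves"].shape == (5, 1)
        assert (res["curves"] == 3).all()

    def test_disjoint_sets_union_arithmetic(self):
        sets = [set(range(3)), set(range(10, 14)), set(range(20, 25))]
        res = saturation_curve(sets, n_shuffles=50, seed=1)
        assert (res["curves"][:, -1] == 12).all()

    def test_monotone_in_every_shuffle_and_deterministic(self, rng):
        sets = [set(rng.integers(0, 50, size=rng.integers(1, 30))) for _ in range(8)]
        res1 = saturation_curve(sets, n_shuffles=100, seed=3)
        res2 = saturation_curve(sets, n_shuffles=100, seed=3)
        assert (np.diff(res1["curves"], axis=1) >= 0).all()
        assert (res1["curves"][:, -1] == res1["union_size"]).all()
        assert np.array_equal(res1["curves"], res2["curves"])

    def test_nested_sets_step_at_largest(self):
        sets = [set(range(2)), set(range(5)), set(range(9))]
        res = saturation_curve(sets, n_shuffles=20, seed=2)
        assert (res["curves"][:, -1] == 9).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            saturation_curve([])


class TestBaseCoverage:
    def single_gene_annotation(self):
        g = GeneModel(
            "G1", "protein_coding", "chrS", "+",
            [Transcript("G1.t1", [(100, 300), (1500, 1700)], cds=(200, 1600))],
            tpm={"cellA": 5.0},
        )
        return Annotation("chrS", 2000, [g])

    def test_full_transcript_peak_covers_pre_mrna(self):
        ann = self.single_gene_annotation()
        peaks = peak_df([("chrS", 100, 1700, "+", 5.0, 5.0)])
        res = base_coverage_by_region([peaks], ann, ["pre-mRNA"])
        assert res["fraction"].iloc[0] == pytest.approx(1.0)

    def test_no_peaks_zero_coverage(self):
        ann = self.single_gene_annotation()
        res = base_coverage_by_region([peak_df([])], ann, ["exon", "intron"])
        assert (res["fraction"] == 0).all()

    def test_two_half_covering_sets_union_to_one(self):
        ann = self.single_gene_annotation()
        first = peak_df([("chrS", 100, 200, "+", 5.0, 5.0)])
        second = peak_df([("chrS", 200, 300, "+", 5.0, 5.0)])
        res = base_coverage_by_region([first, second], ann, ["5'UTR", "CDS"])
        utr = res[res["region_type"] == "5'UTR"]
        assert utr["fraction"].iloc[-1] == pytest.approx(1.0)

    def test_unknown_region_type_rejected(self):
        ann = self.single_gene_annotation()
        with pytest.raises(ValueError):
            base_coverage_by_region([peak_df([])], ann, ["promoter"])
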