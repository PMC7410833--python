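"""Statistics linking binding to expression, chromatin and localization.

Gene-level overlap tests use Fisher's exact test, replaced by the
Yates-corrected chi-square when all observed and expected cell values
exceed 5, with Bonferroni correction across the executed comparison
family.  ChIP-eCLIP comparisons use base-level Jaccard indexes split at
1-kb promoter windows, flank-normalised signal enrichment, and an
expression-matched resampled odds-ratio test.  Localization associations
use one-sided Wilcoxon rank-sum tests on relative information.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .rbns import rank_sum_greater
from .reads import ReadRecord

logger = logging.getLogger(__name__)


# --- effect-size classification ------------------------------------------

def de_classify(log2_fold_change: float) -> str:
    """Strong / moderate / weak differential expression by |log2 FC|.

    Boundaries: strong >= 2, moderate in (1, 2), weak <= 1; significance
    must have been established beforehand.
    """
    m = abs(log2_fold_change)
    if m >= 2:
        return "strong"
    if m > 1:
        return "moderate"
    return "weak"


def splicing_classify(dpsi: float) -> str:
    """Strong (|dpsi| >= 0.30), moderate [0.15, 0.30), weak (0.05, 0.15)."""
    m = abs(dpsi)
    if m <= 0.05:
        raise ValueError("splicing_classify requires |dpsi| > 0.05")
    if m >= 0.30:
        return "strong"
    if m >= 0.15:
        return "moderate"
    return "weak"


def miso_tandem_filter(
    comparisons: Sequence[tuple[float, float]],
    grouped: Sequence[tuple[float, float]],
    min_bf: float = 5.0,
    max_p: float = 0.05,
) -> bool:
    """Significance of a tandem-UTR event from MISO pairwise comparisons.

    ``comparisons`` holds the four (Bayes factor, p) KD-vs-control pairs;
    ``grouped`` holds the two grouped orderings (more-reads KD vs
    fewer-reads control and the reverse).  Significant iff |BF| >= 5 and
    p < 0.05 in all four pairwise comparisons and both groupings.
    """
    if len(comparisons) != 4 or len(grouped) != 2:
        raise ValueError("need 4 pairwise comparisons and 2 grouped orderings")
    for bf, p in list(comparisons) + list(grouped):
        if abs(bf) < min_bf or p >= max_p:
            return False
    return True


# --- expression overlap ---------------------------------------------------

def fisher_or_yates(table: np.ndarray) -> tuple[float, str]:
    """Two-sided p for a 2x2 table: Yates chi-square when all observed and
    expected values exceed 5, else Fisher's exact test."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if table.sum() == 0:
        return 1.0, "none"
    expected = stats.contingency.expected_freq(table)
    if (table > 5).all() and (expected > 5).all():
        return float(stats.chi2_contingency(table, correction=True)[1]), "yates"
    return float(stats.fisher_exact(table, alternative="two-sided")[1]), "fisher"


def expression_overlap(
    bound_genes: set[str],
    de_genes: set[str],
    background: set[str],
    min_de: int = 10,
) -> Optional[dict]:
    """Overlap of region-enriched genes with a DE gene set.

    ``background`` is the eligibility-passing gene universe; the DE set is
    intersected with it.  Skipped (returns None, logged) when at most
    ``min_de`` genes changed.  Bonferroni correction is applied across a
    batch by :func:`expression_overlap_batch`.
    """
    if not background:
        raise ValueError("empty background gene set")
    bound = bound_genes & background
    de = de_genes & background
    if len(de) <= min_de:
        logger.info("DE set of size %d <= %d: comparison skipped", len(de), min_de)
        return None
    a = len(bound & de)
    b = len(bound - de)
    c = len(de - bound)
    d = len(background - bound - de)
    p, method = fisher_or_yates(np.array([[a, b], [c, d]]))
    odds = (a / b) / (c / d) if b and c and d else np.nan
    return {"table": (a, b, c, d), "p": p, "method": method, "odds_ratio": odds}


def expression_overlap_batch(comparisons: dict[str, Optional[dict]]) -> pd.DataFrame:
    """Bonferroni-adjust p-values over the executed (non-skipped) family."""
    executed = {k: v for k, v in comparisons.items() if v is not None}
    m = len(executed)
    rows = []
    for name, res in executed.items():
        rows.append(
            {
                "comparison": name,
                "p": res["p"],
                "p_bonferroni": min(1.0, res["p"] * m),
                "method": res["method"],
                "odds_ratio": res["odds_ratio"],
            }
        )
    return pd.DataFrame(rows)


def ks_by_enrichment(
    fold_changes: pd.Series, categories: pd.Series
) -> dict[tuple[str, str], float]:
    """Two-sided KS p between fold-change distributions per category pair.

    Degenerate categories (< 2 genes) are skipped.
    """
    out: dict[tuple[str, str], float] = {}
    cats = [c for c in categories.unique() if (categories == c).sum() >= 2]
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            xa = fold_changes[categories == a].dropna()
            xb = fold_changes[categories == b].dropna()
            if len(xa) >= 2 and len(xb) >= 2:
                out[(a, b)] = float(stats.ks_2samp(xa, xb).pvalue)
    return out


# --- ChIP / eCLIP comparisons --------------------------------------------

def _interval_mask(intervals: Iterable[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s): min(e, length)] = True
    return mask


def promoter_mask(annotation: Annotation, window: int = 500) -> np.ndarray:
    """1-kb windows centred on every TSS."""
    mask = np.zeros(annotation.length, dtype=bool)
    for g in annotation.genes:
        mask[max(0, g.tss - window): min(g.tss + window, annotation.length)] = True
    return mask


def gene_body_mask(annotation: Annotation, window: int = 500) -> np.ndarray:
    """Gene spans minus the 1-kb windows around TSS and TTS."""
    mask = np.zeros(annotation.length, dtype=bool)
    for g in annotation.genes:
        mask[g.start : g.end] = True
    for g in annotation.genes:
        mask[max(0, g.tss - window): g.tss + window] = False
        mask[max(0, g.tts - window): g.tts + window] = False
    return mask


def jaccard_index(
    set_a: Iterable[tuple[int, int]],
    set_b: Iterable[tuple[int, int]],
    length: int,
    compartment: Optional[np.ndarray] = None,
) -> float:
    """Base-level |A & B| / |A | B|, optionally within a compartment mask."""
    a = _interval_mask(set_a, length)
    b = _interval_mask(set_b, length)
    if compartment is not None:
        a &= compartment
        b &= compartment
    union = (a | b).sum()
    if union == 0:
        logger.info("empty interval union: Jaccard defined as 0")
        return 0.0
    return float((a & b).sum() / union)


def jaccard_matrix(
    peak_sets: dict[str, list[tuple[int, int]]],
    annotation: Annotation,
    promoter_window: int = 500,
) -> dict[str, pd.DataFrame]:
    """Pairwise Jaccard indexes, promoter vs non-promoter compartments."""
    prom = promoter_mask(annotation, promoter_window)
    names = sorted(peak_sets)
    out = {}
    for comp_name, comp in (("promoter", prom), ("non-promoter", ~prom)):
        mat = pd.DataFrame(np.nan, index=names, columns=names)
        for i, a in enumerate(names):
            for b in names[i:]:
                j = jaccard_index(peak_sets[a], peak_sets[b], annotation.length, comp)
                mat.loc[a, b] = mat.loc[b, a] = j
        out[comp_name] = mat
    return out


def chip_at_eclip(
    signal: np.ndarray,
    eclip_peaks: pd.DataFrame,
    gene_body: Optional[np.ndarray] = None,
    flank_factor: int = 10,
    alpha: float = 1e-3,
) -> dict:
    """ChIP signal inside eCLIP peaks vs flanks of 10x the peak length.

    Restricted to gene-body peaks when a mask is given; one-sided rank-sum
    across peaks, significant at p <= 0.001 (no multiple-testing
    correction, by design).
    """
    if (signal < 0).any():
        raise ValueError("signal track must be nonnegative")
    inside, flank = [], []
    truncated = 0
    for row in eclip_peaks.itertuples():
        if gene_body is not None and not gene_body[row.start : row.end].any():
            continue
        L = row.end - row.start
        fs, fe = row.start - flank_factor * L, row.end + flank_factor * L
        if fs < 0 or fe > len(signal):
            truncated += 1
            fs, fe = max(0, fs), min(fe, len(signal))
        inside.append(signal[row.start : row.end].mean())
        left = signal[fs : row.start]
        right = signal[row.end : fe]
        both = np.concatenate([left, right])
        flank.append(both.mean() if len(both) else np.nan)
    inside_arr = np.array(inside)
    flank_arr = np.array(flank)
    ok = np.isfinite(inside_arr) & np.isfinite(flank_arr)
    if ok.sum() < 2 or signal.max() == 0:
        return {"p": float("nan"), "significant": False, "n_peaks": int(ok.sum()),
                "n_truncated": truncated}
    p = rank_sum_greater(inside_arr[ok], flank_arr[ok])
    return {
        "p": p,
        "significant": bool(np.isfinite(p) and p <= alpha),
        "n_peaks": int(ok.sum()),
        "n_truncated": truncated,
    }


def chip_kd_dependence(
    genes: pd.DataFrame,
    n_rounds: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    min_rejections: float = 0.95,
    bound_col: str = "tss_bound",
    de_col: str = "de",
    tpm_col: str = "tpm",
) -> dict:
    """Expression-matched resampled dependence of TSS binding and DE.

    Each round samples equal numbers of bound and unbound genes from the
    same TPM decile, builds the 2x2 table with odds ratio (a/b)/(c/d),
    and applies a one-tailed Fisher test; dependence is declared when the
    null is rejected at ``alpha`` in at least 95% of rounds.
    """
    rng = np.random.default_rng(seed)
    bound = genes[genes[bound_col]]
    unbound = genes[~genes[bound_col]]
    if len(bound) == 0 or len(unbound) == 0:
        return {"verdict": None, "reason": "no bound or no unbound genes"}
    edges = np.quantile(genes[tpm_col], np.linspace(0, 1, 11))

    def decile(values: pd.Series) -> np.ndarray:
        return np.clip(np.searchsorted(edges[1:-1], values, "right"), 0, 9)

    bound_dec = decile(bound[tpm_col])
    unbound_dec = decile(unbound[tpm_col])
    unbound_by_dec = {d: np.nonzero(unbound_dec == d)[0] for d in range(10)}
    take = {
        d: min((bound_dec == d).sum(), len(unbound_by_dec.get(d, ())))
        for d in range(10)
    }
    if sum(take.values()) < 10:
        return {"verdict": None, "reason": "expression matching infeasible"}
    rejections = 0
    odds = []
    for _ in range(n_rounds):
        b_idx, u_idx = [], []
        for d in range(10):
            k = take[d]
            if k == 0:
                continue
            pool_b = np.nonzero(bound_dec == d)[0]
            b_idx.append(rng.choice(pool_b, size=k, replace=False))
            u_idx.append(rng.choice(unbound_by_dec[d], size=k, replace=False))
        bs = bound.iloc[np.concatenate(b_idx)]
        us = unbound.iloc[np.concatenate(u_idx)]
        a = int(bs[de_col].sum())
        b = len(bs) - a
        c = int(us[de_col].sum())
        d_ = len(us) - c
        p = stats.fisher_exact([[a, b], [c, d_]], alternative="greater")[1]
        if p < alpha:
            rejections += 1
        odds.append((a / b) / (c / d_) if b and c and d_ else np.nan)
    return {
        "verdict": rejections >= min_rejections * n_rounds,
        "rejection_rate": rejections / n_rounds,
        "odds_ratios": np.array(odds),
        "n_matched_per_group": sum(take.values()),
    }


# --- localization ---------------------------------------------------------

def localization_association(
    information: pd.DataFrame,
    labels: pd.DataFrame,
    min_group: int = 2,
) -> pd.DataFrame:
    """One-sided rank-sum tests: do RBPs carrying a localization label show
    higher relative information for an RNA class than RBPs without it?

    ``information``: RBP x RNA-class relative information (bits);
    ``labels``: RBP x label booleans.  Splits with an empty side (or below
    ``min_group``) are skipped.
    """
    rows = []
    common = information.index.intersection(labels.index)
    info = information.loc[common]
    labs = labels.loc[common]
    for rna_class in info.columns:
        for label in labs.columns:
            with_l = info.loc[labs[label].astype(bool), rna_class].dropna()
            without = info.loc[~labs[label].astype(bool), rna_class].dropna()
            if len(with_l) < min_group or len(without) < min_group:
                continue
            p = rank_sum_greater(with_l.to_numpy(), without.to_numpy())
            rows.append(
                {
                    "rna_class": rna_class,
                    "label": label,
                    "p": p,
                    "n_with": len(with_l),
                    "n_without": len(without),
                }
            )
    return pd.DataFrame(rows)


def classify_localization(ratio: float) -> str:
    """Nuclear (>= 2), cytoplasmic (<= 0.5) or neither, from the
    nuclear:cytoplasmic staining ratio."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio >= 2:
        return "nuclear"
    if ratio <= 0.5:
        return "cytoplasmic"
    return "neither"


def spliced_unspliced_counts(
    records: Iterable[ReadRecord],
    annotation: Annotation,
    min_overhang: int = 10,
) -> tuple[int, int]:
    """(spliced, unspliced) read counts against annotated junctions.

    Spliced reads span an annotated exon-exon junction with >= 10 nt in
    each exon (requires block-split records); unspliced reads cross an
    exon-intron boundary with >= 10 nt on each side.  Reads shorter than
    2 x the overhang can never qualify.
    """
    junctions = set()
    boundaries = []
    for g in annotation.genes:
        for t in g.transcripts:
            for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
                junctions.add((e1, s2))
            for i_s, i_e in t.introns:
                boundaries.append(i_s)  # exon | intron
                boundaries.append(i_e)  # intron | exon
    boundaries = sorted(set(boundaries))
    spliced = unspliced = 0
    for r in records:
        if r.stop - r.start < 2 * min_overhang:
            continue
        if r.blocks and len(r.blocks) >= 2:
            for (s1, e1), (s2, e2) in zip(r.blocks, r.blocks[1:]):
                if (e1, s2) in junctions and e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                    spliced += 1
                    break
        else:
            for b in boundaries:
                if r.start + min_overhang <= b <= r.stop - min_overhang:
                    unspliced += 1
                    break
    return spliced, unspliced
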