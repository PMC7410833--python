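"""Reproducible peak filtering, annotation, preservation and saturation.

Peaks are rows of a DataFrame (chrom, start, end, strand + per-replicate
log2 fold enrichment and -log10 p).  Replicate-merged scores are geometric
means; the final reproducible set requires merged fold >= 8 and merged
p <= 0.001 after an injectable reproducibility scorer has applied the IDR
cutoff semantics.  Annotation assigns exactly one of the 11 region labels
per peak via the within-gene and cross-gene priority orders.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import (
    Annotation,
    CROSS_GENE_PRIORITY,
    INTERGENIC,
    REGION_LABELS,
    WITHIN_GENE_PRIORITY,
    transcript_region_intervals,
)

PEAK_MIN_FOLD = 8.0
PEAK_MAX_P = 1e-3
IDR_THRESHOLD = 0.01

PEAK_COLUMNS = ["chrom", "start", "end", "strand", "l2fc", "nlp"]


def rank_consistency_scorer(merged: pd.DataFrame) -> np.ndarray:
    """Default reproducibility surrogate.

    Peaks are ranked within each replicate by their enrichment; the
    irreproducibility score is the absolute difference of the two
    normalised ranks (0 for perfectly concordant peaks, approaching 1 for
    discordant ones).  Identical replicates therefore score 0 everywhere.
    """
    n = len(merged)
    if n == 0:
        return np.zeros(0)
    u1 = stats.rankdata(-merged["l2fc_rep1"]) / n
    u2 = stats.rankdata(-merged["l2fc_rep2"]) / n
    return np.abs(u1 - u2)


def reproducible_peaks(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    idr_threshold: float = IDR_THRESHOLD,
    scorer: Optional[Callable[[pd.DataFrame], np.ndarray]] = None,
    min_fold: float = PEAK_MIN_FOLD,
    max_p: float = PEAK_MAX_P,
) -> pd.DataFrame:
    """Merge replicate peaks and apply reproducibility plus score filters.

    The default scorer keeps peaks whose rank-discordance is at most
    sqrt(idr_threshold); a full IDR implementation can be injected through
    ``scorer`` (lower score = more reproducible, cutoff at the same
    threshold semantics).
    """
    if len(rep1) and len(rep2):
        if set(rep1["chrom"]) - set(rep2["chrom"]) and set(rep2["chrom"]) - set(rep1["chrom"]):
            raise ValueError("replicate peak sets are on different references")
    if len(rep1) == 0 or len(rep2) == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    tree: dict[tuple, IntervalTree] = {}
    for i, row in enumerate(rep2.itertuples()):
        tree.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, i
        )
    rows = []
    for row in rep1.itertuples():
        t = tree.get((row.chrom, row.strand))
        if t is None:
            continue
        hits = t.overlap(row.start, row.end)
        if not hits:
            continue
        # best partner = largest overlap
        best = max(
            hits, key=lambda iv: min(iv.end, row.end) - max(iv.begin, row.start)
        )
        other = rep2.iloc[best.data]
        rows.append(
            {
                "chrom": row.chrom,
                "start": min(row.start, int(other["start"])),
                "end": max(row.end, int(other["end"])),
                "strand": row.strand,
                "l2fc_rep1": row.l2fc,
                "nlp_rep1": row.nlp,
                "l2fc_rep2": float(other["l2fc"]),
                "nlp_rep2": float(other["nlp"]),
            }
        )
    if not rows:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    merged = pd.DataFrame(rows)
    merged["l2fc"] = np.sqrt(
        np.clip(merged["l2fc_rep1"], 0, None) * np.clip(merged["l2fc_rep2"], 0, None)
    )
    merged["nlp"] = np.sqrt(
        np.clip(merged["nlp_rep1"], 0, None) * np.clip(merged["nlp_rep2"], 0, None)
    )
    score = (scorer or rank_consistency_scorer)(merged)
    keep = score <= np.sqrt(idr_threshold)
    merged = merged[keep]
    merged = merged[
        (merged["l2fc"] >= np.log2(min_fold)) & (merged["nlp"] >= -np.log10(max_p))
    ]
    return merged.reset_index(drop=True)


def remove_blacklist(
    peaks: pd.DataFrame, blacklist: Iterable[tuple[int, int]] | pd.DataFrame
) -> pd.DataFrame:
    """Drop peaks overlapping (>= 1 nt, strand-blind) any blacklist interval."""
    if isinstance(blacklist, pd.DataFrame):
        intervals = list(zip(blacklist["start"], blacklist["end"]))
    else:
        intervals = list(blacklist)
    if not intervals or len(peaks) == 0:
        return peaks.copy()
    keep = [
        not any(row.start < e and row.end > s for s, e in intervals)
        for row in peaks.itertuples()
    ]
    return peaks[keep].reset_index(drop=True)


def annotate_peak(
    annotation: Annotation, start: int, end: int, strand: str
) -> tuple[str, Optional[str]]:
    """One region label (and host gene) for a peak, by priority.

    Within one gene the within-gene order applies across all its isoform
    region tracks; when several genes are overlapped, each gene's label
    competes under the cross-gene order.  Peaks outside every gene are
    "intergenic".
    """
    hits = annotation.overlapping_regions(start, end, strand)
    if not hits:
        return INTERGENIC, None
    per_gene: list[tuple[int, str, str]] = []
    for gene_id, labels in hits.items():
        label = min(labels, key=WITHIN_GENE_PRIORITY.index)
        per_gene.append((CROSS_GENE_PRIORITY.index(label), gene_id, label))
    per_gene.sort()
    _, gene_id, label = per_gene[0]
    return label, gene_id


def annotate_peaks(annotation: Annotation, peaks: pd.DataFrame) -> pd.DataFrame:
    out = peaks.copy()
    labels, genes = [], []
    for row in peaks.itertuples():
        label, gene = annotate_peak(annotation, row.start, row.end, row.strand)
        labels.append(label)
        genes.append(gene)
    out["label"] = labels
    out["gene_id"] = genes
    return out


def region_fraction_vector(peaks: pd.DataFrame) -> pd.Series:
    """Fraction of peaks per region label (the clustering input vector)."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    counts = peaks["label"].value_counts()
    frac = pd.Series(0.0, index=REGION_LABELS + [INTERGENIC])
    for label, c in counts.items():
        frac[label] = c / len(peaks)
    return frac


# --- cross-cell-type preservation ----------------------------------------

UNCHANGED, WEAK, MODERATE, STRONG = "unchanged", "weak", "moderate", "strong"
CELL_SPECIFIC, OTHER = "cell-type-specific", "other"
EXPRESSION_CATEGORIES = [UNCHANGED, WEAK, MODERATE, STRONG, CELL_SPECIFIC, OTHER]


def categorize_expression(tpm_a: float, tpm_b: float) -> str:
    """Cross-cell expression category from the two TPM values.

    Fold-difference categories (<=1.2 unchanged, <=2 weak, <=5 moderate,
    >5 strong) require TPM >= 1 in both cells; cell-type-specific needs
    TPM < 0.1 in one cell and >= 1 in the other; everything else is other.
    """
    if (tpm_a < 0.1 and tpm_b >= 1) or (tpm_b < 0.1 and tpm_a >= 1):
        return CELL_SPECIFIC
    if tpm_a >= 1 and tpm_b >= 1:
        fold = max(tpm_a, tpm_b) / min(tpm_a, tpm_b)
        if fold <= 1.2:
            return UNCHANGED
        if fold <= 2:
            return WEAK
        if fold <= 5:
            return MODERATE
        return STRONG
    return OTHER


def interval_fold_enrichment(
    ip_cov: np.ndarray,
    input_cov: np.ndarray,
    ip_total: float,
    input_total: float,
    start: int,
    end: int,
) -> float:
    """Depth-normalised IP/input coverage ratio over one interval."""
    ip = ip_cov[start:end].sum() / ip_total if ip_total else 0.0
    inp = input_cov[start:end].sum() / input_total if input_total else 0.0
    if inp == 0:
        return np.inf if ip > 0 else np.nan
    return float(ip / inp)


def cross_cell_preservation(
    peaks: pd.DataFrame,
    ip_cov_b: np.ndarray,
    input_cov_b: np.ndarray,
    ip_total_b: float,
    input_total_b: float,
    expression: pd.DataFrame,
    tpm_cols: tuple[str, str] = ("tpm_a", "tpm_b"),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-peak enrichment in the other cell type plus category summaries.

    Returns (per-peak table, per-category summary with >=4-fold and
    not-enriched fractions, KS p-values between category distributions).
    Peaks whose gene lacks expression data fall into "other".
    """
    per_peak = peaks.copy()
    cats, folds = [], []
    for row in peaks.itertuples():
        gene = getattr(row, "gene_id", None)
        if gene in expression.index:
            cat = categorize_expression(
                float(expression.loc[gene, tpm_cols[0]]),
                float(expression.loc[gene, tpm_cols[1]]),
            )
        else:
            cat = OTHER
        cats.append(cat)
        folds.append(
            interval_fold_enrichment(
                ip_cov_b, input_cov_b, ip_total_b, input_total_b, row.start, row.end
            )
        )
    per_peak["category"] = cats
    per_peak["fold_b"] = folds
    rows = []
    for cat in EXPRESSION_CATEGORIES:
        sub = per_peak[per_peak["category"] == cat]
        if len(sub) == 0:
            continue
        rows.append(
            {
                "category": cat,
                "n_peaks": len(sub),
                "frac_preserved_4fold": float((sub["fold_b"] >= 4).mean()),
                "frac_not_enriched": float((sub["fold_b"] <= 1).mean()),
            }
        )
    summary = pd.DataFrame(rows)
    ks: dict[tuple[str, str], float] = {}
    present = [c for c in EXPRESSION_CATEGORIES if (per_peak["category"] == c).sum() >= 2]
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            xa = per_peak.loc[per_peak["category"] == a, "fold_b"].to_numpy()
            xb = per_peak.loc[per_peak["category"] == b, "fold_b"].to_numpy()
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
            if len(xa) >= 2 and len(xb) >= 2:
                ks[(a, b)] = float(stats.ks_2samp(xa, xb).pvalue)
    return per_peak, summary, ks


# --- saturation ----------------------------------------------------------

def saturation_curve(
    data_sets: Sequence[set], n_shuffles: int = 100, seed: int = 0
) -> dict:
    """Cumulative unique-item curves over shuffled dataset orderings."""
    if len(data_sets) == 0:
        raise ValueError("need at least one data set")
    rng = np.random.default_rng(seed)
    n = len(data_sets)
    curves = np.zeros((n_shuffles, n), dtype=np.int64)
    for s in range(n_shuffles):
        order = rng.permutation(n)
        seen: set = set()
        for j, idx in enumerate(order):
            seen |= data_sets[idx]
            curves[s, j] = len(seen)
    return {
        "curves": curves,
        "mean": curves.mean(axis=0),
        "std": curves.std(axis=0),
        "union_size": len(set().union(*data_sets)),
    }


_REGION_TYPES = [
    "pre-mRNA", "exon", "5'UTR", "CDS", "3'UTR", "intron",
    "splice site", "proximal intron", "distal intron",
]


def _region_mask(
    annotation: Annotation,
    region_type: str,
    transcript_tpm: Optional[dict[str, float]] = None,
) -> np.ndarray:
    """Boolean chromosome mask of a region type over the highest-expressed
    isoform of every gene."""
    if region_type not in _REGION_TYPES:
        raise ValueError(f"unknown region type {region_type!r}")
    mask = np.zeros(annotation.length, dtype=bool)
    for gene in annotation.genes:
        tx = gene.representative_transcript(transcript_tpm)
        if region_type == "pre-mRNA":
            mask[tx.start : tx.end] = True
        elif region_type == "exon":
            for s, e in tx.exons:
                mask[s:e] = True
        elif region_type == "intron":
            for s, e in tx.introns:
                mask[s:e] = True
        elif region_type in ("5'UTR", "CDS", "3'UTR"):
            for s, e, lab in transcript_region_intervals(gene, tx):
                if lab == region_type:
                    mask[s:e] = True
        else:
            for i_s, i_e in tx.introns:
                if region_type == "splice site":
                    mask[i_s : min(i_s + 100, i_e)] = True
                    mask[max(i_e - 100, i_s) : i_e] = True
                elif region_type == "proximal intron":
                    mask[min(i_s + 100, i_e) : min(i_s + 500, i_e)] = True
                    mask[max(i_e - 500, i_s) : max(i_e - 100, i_s)] = True
                else:  # distal intron
                    if i_e - i_s > 1000:
                        mask[i_s + 500 : i_e - 500] = True
    return mask


def base_coverage_by_region(
    peak_sets: Sequence[pd.DataFrame],
    annotation: Annotation,
    region_types: Sequence[str],
    transcript_tpm: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Covered-base fraction per region type for cumulative peak-set
    prefixes, with the fold-increase between successive sizes."""
    masks = {rt: _region_mask(annotation, rt, transcript_tpm) for rt in region_types}
    covered = np.zeros(annotation.length, dtype=bool)
    rows = []
    prev: dict[str, float] = {}
    for i, peaks in enumerate(peak_sets):
        for row in peaks.itertuples():
            covered[max(0, row.start) : min(row.end, annotation.length)] = True
        for rt, mask in masks.items():
            denom = int(mask.sum())
            bases = int((covered & mask).sum())
            frac = bases / denom if denom else 0.0
            fold = bases / prev[rt] if prev.get(rt) else np.nan
            rows.append(
                {
                    "n_sets": i + 1,
                    "region_type": rt,
                    "covered_bases": bases,
                    "fraction": frac,
                    "fold_increase": fold,
                }
            )
            prev[rt] = bases
    return pd.DataFrame(rows)
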