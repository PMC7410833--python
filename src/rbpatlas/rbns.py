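"""RBNS enrichment statistics, iterative masked motif logos, eCLIP k-mer
comparisons, and the RBNS+/- peak stratification machinery.

R values are pulldown k-mer frequencies divided by input frequencies
(overlapping occurrences counted, 0.5 pseudo-occurrences added to every
k-mer in both libraries so absent k-mers never divide by zero).  Z-scores
standardise R across all 4**k k-mers.  Motif logos follow an iterative
mask-and-recount procedure: the top 5mer is weighted by its excess
enrichment R-1, all its occurrences are masked in both libraries, and
enrichments are recomputed until the newly found 5mer's Z-score (computed
from the original, unmasked R values) falls below the threshold.  Accepted
5mers are aligned to the seed, starting a new motif when mismatches plus
offset exceed two, and a split-half (or cross-replicate) filter keeps only
5mers recovered independently in both halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, CDS, DIST_INTRON, PROX_INTRON, SS3, SS5
from .kmers import ReadPool, all_kmers, count_kmers, index_to_kmer, kmer_to_index, mask_kmer

logger = logging.getLogger(__name__)

RBNS_Z_THRESHOLD = 3.0
ECLIP_Z_THRESHOLD = 2.8
MAX_MISMATCH_PLUS_OFFSET = 2
FLANK_PSEUDOCOUNT = 0.25
TRIM_UNALIGNED_FRACTION = 0.75
PEAK_UPSTREAM_EXTENSION = 50


# --- k-mer enrichment profiles -------------------------------------------

@dataclass
class KmerEnrichmentProfile:
    k: int
    pulldown_freq: np.ndarray
    input_freq: np.ndarray
    r: np.ndarray
    z: np.ndarray
    concentration: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": all_kmers(self.k),
                "pulldown_freq": self.pulldown_freq,
                "input_freq": self.input_freq,
                "R": self.r,
                "Z": self.z,
            }
        )

    def top_kmer(self) -> str:
        return index_to_kmer(int(np.argmax(self.r)), self.k)

    def r_of(self, kmer: str) -> float:
        return float(self.r[kmer_to_index(kmer)])

    def z_of(self, kmer: str) -> float:
        return float(self.z[kmer_to_index(kmer)])


def _frequencies(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    c = counts + pseudocount
    return c / c.sum()


def kmer_r_values(
    pulldown: ReadPool,
    inp: ReadPool,
    k: int,
    pseudocount: float = 0.5,
    concentration: str = "",
) -> KmerEnrichmentProfile:
    """Per-k-mer R values and Z-scores for one pulldown/input pair."""
    if len(pulldown) == 0 or len(inp) == 0:
        raise ValueError("empty read set")
    fp = _frequencies(count_kmers(pulldown.array, k), pseudocount)
    fi = _frequencies(count_kmers(inp.array, k), pseudocount)
    r = fp / fi
    sd = r.std()
    z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
    return KmerEnrichmentProfile(k, fp, fi, r, z, concentration)


def select_concentration(profiles: list[KmerEnrichmentProfile]) -> int:
    """Index of the profile with the highest single-k-mer R value."""
    if not profiles:
        raise ValueError("no profiles")
    return int(np.argmax([p.r.max() for p in profiles]))


# --- iterative masked logo discovery -------------------------------------

@dataclass
class MotifLogo:
    """Aligned k-mers with weights and the derived position weight matrix."""

    members: list[tuple[str, float, int]]  # (kmer, weight R-1, offset vs seed)
    pwm: np.ndarray  # (width, 4) columns over A/C/G/U, each summing to 1
    motif_fraction: float
    trimmed_positions: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def seed(self) -> str:
        return self.members[0][0]

    @property
    def kmers(self) -> set[str]:
        return {m[0] for m in self.members}

    @property
    def total_weight(self) -> float:
        return sum(m[1] for m in self.members)

    def consensus(self) -> str:
        return "".join("ACGU"[i] for i in self.pwm.argmax(axis=1))


def iterative_enriched_kmers(
    pulldown: ReadPool,
    inp: ReadPool,
    k: int = 5,
    z_threshold: float = RBNS_Z_THRESHOLD,
    pseudocount: float = 0.5,
) -> list[tuple[str, float]]:
    """Mask-and-recount loop; returns accepted (kmer, weight=R-1) in order."""
    original = kmer_r_values(pulldown, inp, k, pseudocount)
    pull = pulldown.copy()
    ip = inp.copy()
    accepted: list[tuple[str, float]] = []
    for _ in range(4**k):
        prof = kmer_r_values(pull, ip, k, pseudocount)
        top_idx = int(np.argmax(prof.r))  # ties resolve lexicographically
        top = index_to_kmer(top_idx, k)
        if original.z[top_idx] < z_threshold:
            break
        weight = float(prof.r[top_idx]) - 1.0
        if weight <= 0:
            break
        n_masked = mask_kmer(pull.array, top)
        mask_kmer(ip.array, top)
        accepted.append((top, weight))
        if n_masked == 0:
            break  # nothing left to mask: further recounts cannot change
    return accepted


def _best_alignment(kmer: str, seed: str) -> tuple[int, int]:
    """(cost, offset) minimising mismatches + |offset|; |offset| ties prefer
    upstream shifts, then the smaller cost wins."""
    k = len(seed)
    best = (10**9, 0)
    offsets = sorted(range(-(k - 1), k), key=lambda o: (abs(o), o))
    for off in offsets:
        mism = sum(
            1
            for i in range(k)
            if 0 <= i + off < k and kmer[i] != seed[i + off]
        )
        cost = mism + abs(off)
        if cost < best[0]:
            best = (cost, off)
    return best


def align_kmers(accepted: list[tuple[str, float]]) -> list[list[tuple[str, float, int]]]:
    """Greedy alignment of accepted k-mers into motifs (seed = first member)."""
    motifs: list[list[tuple[str, float, int]]] = []
    for kmer, weight in accepted:
        placed = False
        for motif in motifs:
            cost, off = _best_alignment(kmer, motif[0][0])
            if cost <= MAX_MISMATCH_PLUS_OFFSET:
                motif.append((kmer, weight, off))
                placed = True
                break
        if not placed:
            motifs.append([(kmer, weight, 0)])
    return motifs


def _build_pwm(members: list[tuple[str, float, int]]) -> tuple[np.ndarray, int]:
    k = len(members[0][0])
    offs = [m[2] for m in members]
    mn, mx = min(offs), max(offs)
    width = k + (mx - mn)
    counts = np.zeros((width, 4))
    unaligned = np.zeros(width)
    total = 0.0
    for kmer, weight, off in members:
        total += weight
        start = off - mn
        covered = np.zeros(width, dtype=bool)
        for i, c in enumerate(kmer):
            counts[start + i, "ACGU".index(c)] += weight
            covered[start + i] = True
        counts[~covered] += FLANK_PSEUDOCOUNT * weight
        unaligned[~covered] += weight
    lo, hi = 0, width
    while hi - lo > k and unaligned[lo] / total > TRIM_UNALIGNED_FRACTION:
        lo += 1
    while hi - lo > k and unaligned[hi - 1] / total > TRIM_UNALIGNED_FRACTION:
        hi -= 1
    pwm = counts[lo:hi]
    pwm = pwm / pwm.sum(axis=1, keepdims=True)
    return pwm, width - (hi - lo)


def _logos_from_members(
    motifs: list[list[tuple[str, float, int]]], metadata: dict
) -> list[MotifLogo]:
    total = sum(w for motif in motifs for _, w, _ in motif)
    logos = []
    for motif in motifs:
        pwm, trimmed = _build_pwm(motif)
        logos.append(
            MotifLogo(
                members=motif,
                pwm=pwm,
                motif_fraction=sum(w for _, w, _ in motif) / total if total else 0.0,
                trimmed_positions=trimmed,
                metadata=dict(metadata),
            )
        )
    logos.sort(key=lambda m: -m.total_weight)
    return logos


def _split_filtered_logos(
    full_pull: ReadPool,
    full_inp: ReadPool,
    halves: list[tuple[ReadPool, ReadPool]],
    k: int,
    z_threshold: float,
    metadata: dict,
) -> list[MotifLogo]:
    half_sets = []
    for pull_h, inp_h in halves:
        half_sets.append({km for km, _ in iterative_enriched_kmers(pull_h, inp_h, k, z_threshold)})
    accepted = iterative_enriched_kmers(full_pull, full_inp, k, z_threshold)
    kept = [
        (km, w) for km, w in accepted if all(km in hs for hs in half_sets)
    ]
    if not kept:
        return []
    return _logos_from_members(align_kmers(kept), metadata)


def build_rbns_logos(
    pulldown: ReadPool,
    inp: ReadPool,
    k: int = 5,
    z_threshold: float = RBNS_Z_THRESHOLD,
) -> list[MotifLogo]:
    """Iterative masked logos with the split-half robustness filter."""
    p1, p2 = pulldown.split_halves()
    i1, i2 = inp.split_halves()
    return _split_filtered_logos(
        pulldown, inp, [(p1, i1), (p2, i2)], k, z_threshold, {"source": "rbns"}
    )


def build_eclip_logos(
    rep1_seqs: ReadPool,
    rep2_seqs: ReadPool,
    background1: ReadPool,
    background2: ReadPool,
    k: int = 5,
    z_threshold: float = ECLIP_Z_THRESHOLD,
    region: str = "all",
) -> list[MotifLogo]:
    """eCLIP logos: replicate peak sets play the role of the RBNS halves."""
    if len(rep1_seqs) == 0 or len(rep2_seqs) == 0:
        return []
    full_pull = ReadPool.from_sequences(
        list(rep1_seqs.sequences()) + list(rep2_seqs.sequences())
    )
    full_bg = ReadPool.from_sequences(
        list(background1.sequences()) + list(background2.sequences())
    )
    return _split_filtered_logos(
        full_pull,
        full_bg,
        [(rep1_seqs, background1), (rep2_seqs, background2)],
        k,
        z_threshold,
        {"source": "eclip", "region": region},
    )


# --- eCLIP k-mer Z-scores and motif overlap ------------------------------

def eclip_kmer_zscores(
    peak_seqs: ReadPool, background_seqs: ReadPool, k: int
) -> np.ndarray:
    """Z-scores of real-minus-background k-mer frequency differences."""
    if len(peak_seqs) < 2:
        raise ValueError("need at least two peaks to compute k-mer Z-scores")
    freal = _frequencies(count_kmers(peak_seqs.array, k), 0.5)
    fbg = _frequencies(count_kmers(background_seqs.array, k), 0.5)
    diff = freal - fbg
    sd = diff.std()
    if sd == 0:
        return np.zeros_like(diff)
    return (diff - diff.mean()) / sd


def motif_overlap_test(rbns_kmers: set[str], eclip_kmers: set[str], k: int = 5) -> float:
    """Upper-tail hypergeometric p of the overlap against all 4**k k-mers."""
    universe = 4**k
    if not rbns_kmers or not eclip_kmers:
        return 1.0
    n_a, n_b = len(rbns_kmers), len(eclip_kmers)
    overlap = len(rbns_kmers & eclip_kmers)
    # P(X >= overlap), X ~ Hypergeom(universe, n_a, n_b)
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


# --- peak sequence handling and RBNS+/- stratification -------------------

def peak_sequences(
    annotation: Annotation,
    peaks: pd.DataFrame,
    extend_upstream: int = PEAK_UPSTREAM_EXTENSION,
) -> list[str]:
    """Sense-strand sequences of peaks, extended upstream of their 5' ends."""
    seqs = []
    for row in peaks.itertuples():
        if row.strand == "+":
            s, e = row.start - extend_upstream, row.end
        else:
            s, e = row.start, row.end + extend_upstream
        seqs.append(annotation.region_sequence(max(0, s), e, row.strand))
    return seqs


def classify_peaks_by_motif(
    annotation: Annotation,
    peaks: pd.DataFrame,
    top_kmer: str,
    extend_upstream: int = PEAK_UPSTREAM_EXTENSION,
) -> np.ndarray:
    """True (RBNS+) where the extended peak contains the top RBNS k-mer."""
    motif = top_kmer.upper().replace("T", "U")
    return np.array(
        [motif in s for s in peak_sequences(annotation, peaks, extend_upstream)]
    )


def matched_background_intervals(
    annotation: Annotation, peaks: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Shuffled background peaks preserving gene, region class and length.

    Intronic and CDS peaks preserve the peak start's distance to the
    closest intron-exon boundary; UTR and exonic peaks move uniformly
    within same-label intervals of the gene.  Peaks without a feasible
    background position are dropped (logged).
    """
    from .annotation import transcript_region_intervals

    rng = np.random.default_rng(seed)
    rows = []
    for row in peaks.itertuples():
        gene = annotation.gene(row.gene_id)
        tx = gene.representative_transcript()
        length = row.end - row.start
        regions = [
            (s, e)
            for s, e, lab in transcript_region_intervals(gene, tx)
            if lab == row.label and e - s >= length
        ]
        candidates: list[int] = []
        if row.label in (CDS, PROX_INTRON, DIST_INTRON, SS5, SS3):
            boundaries = sorted(
                {b for s, e in tx.exons for b in (s, e)}
            )
            d = min(abs(row.start - b) for b in boundaries)
            sign = rng.integers(0, 2) * 2 - 1
            for b in boundaries:
                for sgn in (sign, -sign):
                    cand = b + sgn * d
                    if any(s <= cand and cand + length <= e for s, e in regions):
                        candidates.append(int(cand))
        else:
            for s, e in regions:
                candidates.extend(range(s, e - length + 1))
        if not candidates:
            logger.info("no background position for peak %s:%s-%s (%s)",
                        row.gene_id, row.start, row.end, row.label)
            continue
        start = int(candidates[rng.integers(0, len(candidates))])
        rows.append(
            {
                "chrom": annotation.chrom,
                "start": start,
                "end": start + length,
                "strand": row.strand,
                "gene_id": row.gene_id,
                "label": row.label,
            }
        )
    return pd.DataFrame(rows)


def matched_controls(
    positives: pd.DataFrame,
    candidates: pd.DataFrame,
    expression_col: str = "tpm",
    psi_col: str = "psi_control",
    seed: int = 0,
) -> pd.DataFrame:
    """One control event per positive, matched on joint deciles of
    wild-type expression and psi, sampled without replacement."""
    rng = np.random.default_rng(seed)
    pool = pd.concat([positives[[expression_col, psi_col]],
                      candidates[[expression_col, psi_col]]])
    expr_edges = np.quantile(pool[expression_col], np.linspace(0, 1, 11))
    psi_edges = np.quantile(pool[psi_col], np.linspace(0, 1, 11))

    def cell(df: pd.DataFrame) -> pd.Series:
        e = np.clip(np.searchsorted(expr_edges[1:-1], df[expression_col], "right"), 0, 9)
        p = np.clip(np.searchsorted(psi_edges[1:-1], df[psi_col], "right"), 0, 9)
        return pd.Series(list(zip(e, p)), index=df.index)

    pos_cells = cell(positives)
    cand_cells = cell(candidates)
    available: dict = {}
    for idx, c in cand_cells.items():
        available.setdefault(c, []).append(idx)
    chosen = []
    for _, c in pos_cells.items():
        bucket = available.get(c, [])
        if not bucket:
            logger.info("no matched control in decile cell %s; positive dropped", c)
            continue
        j = int(rng.integers(0, len(bucket)))
        chosen.append(bucket.pop(j))
    return candidates.loc[chosen]


def rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p that x is stochastically greater.

    Exact enumeration for small tie-free samples, normal approximation
    with tie correction otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    small = min(len(x), len(y)) <= 25
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def splicing_effect_compare(
    dpsi_peak_motif: np.ndarray,
    dpsi_peak_only: np.ndarray,
    dpsi_no_peak: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Compare |dpsi| for peak-bearing vs matched control exons.

    The primary test pools peak+motif and peak-only exons against matched
    no-peak controls; when significant, peaks are split by top-RBNS-5mer
    presence and re-tested against each other.
    """
    dpsi_peak_motif = np.asarray(dpsi_peak_motif, float)
    dpsi_peak_only = np.asarray(dpsi_peak_only, float)
    dpsi_no_peak = np.asarray(dpsi_no_peak, float)
    peak_all = np.concatenate([dpsi_peak_motif, dpsi_peak_only])
    p_peak = rank_sum_greater(np.abs(peak_all), np.abs(dpsi_no_peak))
    out = {
        "p_peak_vs_control": p_peak,
        "p_motif_vs_nomotif": float("nan"),
        "cdf": {
            "peak+motif": np.sort(dpsi_peak_motif),
            "peak-only": np.sort(dpsi_peak_only),
            "no-peak": np.sort(dpsi_no_peak),
        },
        "n": {
            "peak+motif": len(dpsi_peak_motif),
            "peak-only": len(dpsi_peak_only),
            "no-peak": len(dpsi_no_peak),
        },
    }
    if np.isfinite(p_peak) and p_peak < alpha:
        out["p_motif_vs_nomotif"] = rank_sum_greater(
            np.abs(dpsi_peak_motif), np.abs(dpsi_peak_only)
        )
    return out
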