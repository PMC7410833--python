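"""Input-normalised RNA splicing maps around knockdown-responsive events.

A splicing map averages per-position eCLIP density (IP minus input, both in
reads per million) over a meta-region built from the splice-site boundaries
of significant events, subtracts the mean over "native" events (cassette
exons with control inclusion between 0.05 and 0.95), and frames the result
with the 0.5th/99.5th percentile band of means from repeated random
samplings of native events of matched size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_SAMPLINGS = 1000
MIN_EVENTS = {"SE": 100, "A3SS": 50, "A5SS": 50}
BAND_PERCENTILES = (0.5, 99.5)

EVENT_COLUMNS = [
    "event_id", "event_type", "gene_id", "chrom", "strand",
    "exon_start", "exon_end", "upstream_es", "upstream_ee",
    "downstream_es", "downstream_ee",
    "psi_control", "psi_kd", "dpsi", "pvalue", "fdr",
]


@dataclass
class MapWindows:
    exonic: int = 50
    intronic: int = 300

    @property
    def per_boundary(self) -> int:
        return self.exonic + self.intronic

    @property
    def length(self) -> int:
        return 4 * self.per_boundary


def filter_events(
    events: pd.DataFrame,
    max_p: float = 0.05,
    max_fdr: float = 0.1,
    min_dpsi: float = 0.05,
    native_band: tuple[float, float] = (0.05, 0.95),
) -> dict[str, pd.DataFrame]:
    """Split an event table into KD-included, KD-excluded and native sets.

    Significant events satisfy p < 0.05, FDR < 0.1 and |dpsi| > 0.05;
    direction follows the sign of dpsi (positive = more included upon
    knockdown).  Native cassette exons have control psi inside the stated
    band and are not significant.
    """
    for col in ("pvalue", "fdr", "dpsi", "psi_control"):
        if col not in events.columns:
            raise ValueError(f"event table lacks required column {col!r}")
    sig = (
        (events["pvalue"] < max_p)
        & (events["fdr"] < max_fdr)
        & (events["dpsi"].abs() > min_dpsi)
    )
    native = (
        ~sig
        & (events["psi_control"] > native_band[0])
        & (events["psi_control"] < native_band[1])
    )
    return {
        "included": events[sig & (events["dpsi"] > 0)].reset_index(drop=True),
        "excluded": events[sig & (events["dpsi"] < 0)].reset_index(drop=True),
        "native": events[native].reset_index(drop=True),
    }


def meta_positions(event, windows: MapWindows) -> np.ndarray:
    """Genomic position indices of the meta-region, -1 where masked.

    Four boundaries in transcript orientation: upstream-exon end, event
    5' splice site region, event 3' end, downstream-exon start; each
    contributes ``exonic`` exon positions and ``intronic`` intron
    positions.  Positions beyond the actual feature are masked (-1), not
    zero-filled.  Minus-strand events are mirrored so that left is always
    transcript-upstream.
    """
    ex, In = windows.exonic, windows.intronic
    ues, uee = int(event.upstream_es), int(event.upstream_ee)
    es, ee = int(event.exon_start), int(event.exon_end)
    des, dee = int(event.downstream_es), int(event.downstream_ee)

    def seg(start: int, stop: int, lo: int, hi: int, width: int, align: str) -> np.ndarray:
        pos = np.arange(start, stop)
        pos[(pos < lo) | (pos >= hi)] = -1
        if align == "right":
            out = np.full(width, -1, dtype=np.int64)
            out[width - len(pos):] = pos
        else:
            out = np.full(width, -1, dtype=np.int64)
            out[: len(pos)] = pos
        return out

    # genomic-left to genomic-right boundary layout
    segs = [
        np.concatenate([
            seg(uee - ex, uee, ues, uee, ex, "right"),
            seg(uee, uee + In, uee, es, In, "left"),
        ]),
        np.concatenate([
            seg(es - In, es, uee, es, In, "right"),
            seg(es, es + ex, es, ee, ex, "left"),
        ]),
        np.concatenate([
            seg(ee - ex, ee, es, ee, ex, "right"),
            seg(ee, ee + In, ee, des, In, "left"),
        ]),
        np.concatenate([
            seg(des - In, des, ee, des, In, "right"),
            seg(des, des + ex, des, dee, ex, "left"),
        ]),
    ]
    vec = np.concatenate(segs)
    if event.strand == "-":
        vec = vec[::-1]
    return vec


def event_density(
    ip_cov: np.ndarray,
    input_cov: np.ndarray,
    ip_total: float,
    input_total: float,
    event,
    windows: MapWindows | None = None,
    mode: str = "difference",
) -> np.ndarray:
    """Per-position normalised density over the event meta-region.

    Default combiner is IP RPM minus input RPM; ``mode='ratio'`` divides
    instead (with a one-RPM floor on the denominator).
    """
    windows = windows or MapWindows()
    idx = meta_positions(event, windows)
    valid = (idx >= 0) & (idx < len(ip_cov))
    out = np.full(windows.length, np.nan)
    ip_rpm = ip_cov[idx[valid]] / ip_total * 1e6 if ip_total else 0.0
    in_rpm = input_cov[idx[valid]] / input_total * 1e6 if input_total else 0.0
    if mode == "difference":
        out[valid] = ip_rpm - in_rpm
    elif mode == "ratio":
        out[valid] = ip_rpm / np.maximum(in_rpm, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def normalize_per_event(matrix: np.ndarray) -> np.ndarray:
    """Scale each event's density vector by its total absolute mass.

    Prevents a few highly expressed genes from dominating the event
    average; events with no signal are left untouched.
    """
    scale = np.nansum(np.abs(matrix), axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return matrix / scale


def density_matrix(
    events: pd.DataFrame,
    ip_cov: np.ndarray,
    input_cov: np.ndarray,
    ip_total: float,
    input_total: float,
    windows: MapWindows | None = None,
    mode: str = "difference",
    per_event_norm: bool = True,
) -> np.ndarray:
    windows = windows or MapWindows()
    if len(events) == 0:
        return np.empty((0, windows.length))
    mat = np.vstack(
        [
            event_density(ip_cov, input_cov, ip_total, input_total, ev, windows, mode)
            for ev in events.itertuples()
        ]
    )
    return normalize_per_event(mat) if per_event_norm else mat


@dataclass
class SplicingMap:
    values: np.ndarray  # native-normalised mean density, per position
    band_lo: np.ndarray
    band_hi: np.ndarray
    background_mean: np.ndarray
    n_events: int
    event_class: str = ""
    windows: MapWindows = field(default_factory=MapWindows)

    def escapes_band(self) -> np.ndarray:
        return (self.values < self.band_lo) | (self.values > self.band_hi)


def splicing_map(
    event_densities: np.ndarray,
    native_densities: np.ndarray,
    n_samplings: int = N_SAMPLINGS,
    seed: int = 0,
    min_events: int = MIN_EVENTS["SE"],
    event_class: str = "",
    windows: MapWindows | None = None,
) -> SplicingMap:
    """Native-normalised mean density with a resampled percentile band."""
    n_events = len(event_densities)
    if n_events < min_events:
        raise ValueError(
            f"too few events for a splicing map: {n_events} < {min_events}"
        )
    n_native = len(native_densities)
    if n_native == 0:
        raise ValueError("no native events")
    rng = np.random.default_rng(seed)
    import warnings

    with warnings.catch_warnings():
        # positions masked in every event stay NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        native_mean = np.nanmean(native_densities, axis=0)
        values = np.nanmean(event_densities, axis=0) - native_mean

    filled = np.nan_to_num(native_densities, nan=0.0)
    valid = np.isfinite(native_densities).astype(float)
    size = min(n_events, n_native)
    if size < n_native:
        # without-replacement sampling of matched size per round
        W = np.zeros((n_samplings, n_native))
        ranks = rng.random((n_samplings, n_native)).argsort(axis=1)[:, :size]
        np.put_along_axis(W, ranks, 1.0, axis=1)
    else:
        # matched size exhausts the native pool: bootstrap instead, so the
        # band keeps a nonzero width
        W = rng.multinomial(size, np.full(n_native, 1.0 / n_native),
                            size=n_samplings).astype(float)
    sums = W @ filled
    counts = W @ valid
    with np.errstate(invalid="ignore", divide="ignore"):
        sample_means = sums / counts - native_mean
    lo, hi = np.nanpercentile(sample_means, BAND_PERCENTILES, axis=0)
    return SplicingMap(
        values=values,
        band_lo=lo,
        band_hi=hi,
        background_mean=native_mean,
        n_events=n_events,
        event_class=event_class,
        windows=windows or MapWindows(),
    )


def map_correlation(
    maps_a: dict[str, SplicingMap | None],
    maps_b: dict[str, SplicingMap | None],
    min_events: dict[str, int] | None = None,
) -> float:
    """Pearson r between two RBPs' splicing-map vectors.

    The vectors concatenate the KD-included and KD-excluded maps; a class
    below its minimum event count in either RBP is dropped, and NaN when
    no class qualifies.
    """
    min_events = min_events or MIN_EVENTS
    xs, ys = [], []
    for cls in ("included", "excluded"):
        a, b = maps_a.get(cls), maps_b.get(cls)
        if a is None or b is None:
            continue
        need = min_events.get(a.event_class or "SE", MIN_EVENTS["SE"])
        if a.n_events < need or b.n_events < need:
            continue
        xs.append(a.values)
        ys.append(b.values)
    if not xs:
        return float("nan")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def class_average_map(maps: list[SplicingMap]) -> dict:
    """Mean cross-RBP map with a 10th-90th percentile spread."""
    if not maps:
        raise ValueError("empty binding class")
    stack = np.vstack([m.values for m in maps])
    return {
        "mean": np.nanmean(stack, axis=0),
        "p10": np.nanpercentile(stack, 10, axis=0),
        "p90": np.nanpercentile(stack, 90, axis=0),
        "n_rbps": len(maps),
    }


def rbp_per_exon_profile(
    peak_sets: list[pd.DataFrame],
    exons: pd.DataFrame,
    chrom_length: int,
    windows: MapWindows | None = None,
) -> np.ndarray:
    """Average number of RBPs with a peak at each meta-exon position.

    ``peak_sets`` holds one reproducible peak table per RBP (spliceosomal
    RBPs should be excluded upstream); peaks match events on strand.
    """
    windows = windows or MapWindows()
    if len(exons) == 0:
        raise ValueError("empty exon set")
    masks = []
    for peaks in peak_sets:
        per_strand = {"+": np.zeros(chrom_length, dtype=bool),
                      "-": np.zeros(chrom_length, dtype=bool)}
        for row in peaks.itertuples():
            per_strand[row.strand][max(0, row.start): min(row.end, chrom_length)] = True
        masks.append(per_strand)
    total = np.zeros(windows.length)
    for ev in exons.itertuples():
        idx = meta_positions(ev, windows)
        valid = (idx >= 0) & (idx < chrom_length)
        for per_strand in masks:
            hit = np.zeros(windows.length)
            hit[valid] = per_strand[ev.strand][idx[valid]]
            total += hit
    return total / len(exons)
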