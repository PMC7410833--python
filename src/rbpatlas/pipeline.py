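"""End-to-end pipeline: simulate, quantify, call, discover, map, integrate.

Every stage draws randomness from child seeds derived from the single run
seed, and every output is written in a deterministic text format, so two
runs with the same configuration produce byte-identical artifact
directories (recorded, with per-file SHA-256 digests, in the manifest).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, integrate, io, peaks as peakmod, repeats, splicemaps
from .annotation import Annotation, transcript_region_intervals, CDS, UTR3
from .config import RunConfig
from .rbns import build_rbns_logos, kmer_r_values
from .simulate import (
    BindingTruth,
    coverage_from_records,
    make_transcriptome,
    simulate_chip,
    simulate_eclip,
    simulate_kd_tables,
    simulate_rbns,
)


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def default_truth(annotation: Annotation, config: RunConfig, rng) -> BindingTruth:
    """Plant enrichment in 3'UTRs and downstream proximal introns of a
    deterministic subset of coding genes, tied to planted regulation."""
    elements = []
    regulation = {}
    de_genes = {}
    coding = [g for g in annotation.genes if g.gene_type == "protein_coding"]
    for i, g in enumerate(coding):
        if i % 2 == 0:
            de_genes[g.gene_id] = float(rng.normal(2.0, 0.3)) * (1 if i % 4 else -1)
        if i % 3 != 0:
            continue
        t = g.transcripts[0]
        want = UTR3 if i % 6 == 0 else CDS
        for s, e, lab in transcript_region_intervals(g, t):
            # keep CDS elements clear of the 1-kb TSS/TTS windows so some
            # peaks survive the gene-body restriction downstream
            interior = lab == UTR3 or (s > g.start + 600 and e < g.end - 600)
            if lab == want and e - s >= 100 and interior:
                elements.append((s, e, config.planted_fold))
                break
        if len(t.exons) >= 3:
            regulation[(g.gene_id, 1)] = 0.3 if i % 6 == 0 else -0.3
    family_weights = {"RNA18S": 4.0} if config.n_repeat_families >= 1 else {}
    return BindingTruth(
        enriched_elements=elements,
        family_weights=family_weights,
        motif=config.rbns_motif,
        selection=config.rbns_selection,
        regulation=regulation,
        de_genes=de_genes,
    )


def call_candidate_peaks(
    annotation: Annotation,
    records: list,
    input_records: list,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Region-level candidate peaks from one IP replicate vs input.

    Scans every labelled transcript region, computes fold enrichment and
    a Fisher/Yates p with the region eligibility rule, and emits enriched
    regions as candidate peaks carrying (log2FC, -log10 p).
    """
    ip_cov, ip_n = coverage_from_records(records, annotation.length, annotation.chrom)
    in_cov, in_n = coverage_from_records(
        input_records, annotation.length, annotation.chrom
    )
    read_len = 50
    rows = []
    for g in annotation.genes:
        t = g.transcripts[0]
        for s, e, lab in transcript_region_intervals(g, t):
            s, e = max(0, s), min(e, annotation.length)
            if e <= s:
                continue
            ipc = int(round(ip_cov[s:e].sum() / read_len))
            inc = int(round(in_cov[s:e].sum() / read_len))
            fold, p, eligible = repeats.quantify_region(ipc, inc, ip_n, in_n)
            if eligible and np.isfinite(fold) and fold >= min_fold:
                rows.append(
                    {
                        "chrom": annotation.chrom,
                        "start": s,
                        "end": e,
                        "strand": g.strand,
                        "l2fc": float(np.log2(fold)) if fold > 0 else 0.0,
                        "nlp": float(-np.log10(max(p, 1e-300))),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "l2fc", "nlp"])


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on synthetic data; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- stage 0: annotation + truth
    annotation, db = make_transcriptome(
        config.n_genes, config.n_repeat_families, seed=_child_seed(seed, 0)
    )
    truth = default_truth(
        annotation, config, np.random.default_rng(_child_seed(seed, 1))
    )

    # --- stage 1: eCLIP simulation and repeat quantification
    rep1, rep2, inp = simulate_eclip(
        annotation, truth, config.eclip_depth, config.dup_rate,
        seed=_child_seed(seed, 2), db=db,
    )
    io.write_read_records(rep1, out / "eclip_ip_rep1.tsv")
    io.write_read_records(rep2, out / "eclip_ip_rep2.tsv")
    io.write_read_records(inp, out / "eclip_input.tsv")

    rep1_d = repeats.dedup_pcr(rep1)
    rep2_d = repeats.dedup_pcr(rep2)
    inp_d = repeats.dedup_pcr(inp)

    def assignments(records):
        out_asg = []
        for r in records:
            if r.target == annotation.chrom:
                continue
            a = repeats.assign_family([r], db)
            if a:
                out_asg.append(a)
        return out_asg

    fq = repeats.quantify_families(
        assignments(rep1_d), assignments(inp_d), len(rep1_d), len(inp_d)
    )
    fq.to_tsv(out / "family_quant.tsv")

    # --- stage 2: peaks
    cand1 = call_candidate_peaks(annotation, rep1_d, inp_d)
    cand2 = call_candidate_peaks(annotation, rep2_d, inp_d)
    repro = peakmod.reproducible_peaks(
        cand1, cand2, idr_threshold=config.idr_threshold,
        min_fold=config.peak_min_fold, max_p=config.peak_max_p,
    )
    if config.blacklist_path:
        blacklist = io.read_bed(config.blacklist_path)
        repro = peakmod.remove_blacklist(repro, blacklist)
    repro = peakmod.annotate_peaks(annotation, repro)
    io.write_table(repro, out / "reproducible_peaks.tsv")
    if len(repro):
        peakmod.region_fraction_vector(repro).rename("fraction").to_csv(
            out / "region_fractions.tsv", sep="\t"
        )

    # --- stage 3: RBNS
    pull, rbns_in = simulate_rbns(
        config.rbns_motif, config.rbns_selection, config.rbns_reads,
        config.rbns_read_len, seed=_child_seed(seed, 3),
    )
    pull.to_fasta(out / "rbns_pulldown.fasta")
    rbns_in.to_fasta(out / "rbns_input.fasta")
    profile = kmer_r_values(pull, rbns_in, k=5)
    profile.as_frame().to_csv(out / "rbns_5mer_enrichment.tsv", sep="\t", index=False)
    logos = build_rbns_logos(pull, rbns_in, k=5, z_threshold=config.rbns_z_threshold)
    with open(out / "rbns_logos.tsv", "w") as fh:
        fh.write("logo\tkmer\tweight\toffset\tconsensus\tmotif_fraction\n")
        for i, logo in enumerate(logos):
            for kmer, w, off in logo.members:
                fh.write(
                    f"{i}\t{kmer}\t{w!r}\t{off}\t{logo.consensus()}"
                    f"\t{logo.motif_fraction!r}\n"
                )

    # --- stage 4: KD tables and splicing map
    events, genes = simulate_kd_tables(
        annotation, truth, config.n_events, seed=_child_seed(seed, 4)
    )
    io.write_table(events, out / "kd_splicing_events.tsv")
    io.write_table(genes, out / "kd_gene_expression.tsv")
    groups = splicemaps.filter_events(
        events, min_dpsi=config.min_dpsi, native_band=config.native_psi_band
    )
    ip_cov, ip_n = coverage_from_records(rep1_d, annotation.length, annotation.chrom)
    in_cov, in_n = coverage_from_records(inp_d, annotation.length, annotation.chrom)
    windows = splicemaps.MapWindows(config.exonic_window, config.intronic_window)
    map_rows = []
    for cls in ("included", "excluded"):
        ev = groups[cls]
        nat = groups["native"]
        if len(ev) == 0 or len(nat) == 0:
            continue
        dens = splicemaps.density_matrix(ev, ip_cov, in_cov, ip_n, in_n, windows)
        nat_dens = splicemaps.density_matrix(nat, ip_cov, in_cov, ip_n, in_n, windows)
        try:
            smap = splicemaps.splicing_map(
                dens, nat_dens, n_samplings=config.n_samplings,
                seed=_child_seed(seed, 5), min_events=min(20, len(dens)),
                event_class="SE", windows=windows,
            )
        except ValueError:
            continue
        for pos in range(windows.length):
            map_rows.append(
                {
                    "class": cls,
                    "position": pos,
                    "value": smap.values[pos],
                    "band_lo": smap.band_lo[pos],
                    "band_hi": smap.band_hi[pos],
                }
            )
    pd.DataFrame(map_rows).to_csv(out / "splicing_map.tsv", sep="\t",
                                  index=False, float_format="%.10g")

    # --- stage 5: integration
    chip_peaks, chip_signal = simulate_chip(
        annotation, config.promoter_bias, seed=_child_seed(seed, 6),
        n_peaks=config.chip_peaks,
    )
    io.write_bed(chip_peaks, out / "chip_peaks.bed")
    io.write_bedgraph(chip_signal, out / "chip_signal.bedgraph", annotation.chrom)

    results: dict = {}
    de_set = set(genes.loc[(genes["padj"] < 0.05), "gene_id"])
    bound = set(repro["gene_id"].dropna()) if len(repro) else set()
    background = set(genes["gene_id"])
    ov = integrate.expression_overlap(bound, de_set, background)
    if ov is not None:
        results["expression_overlap_p"] = ov["p"]
        results["expression_overlap_odds"] = ov["odds_ratio"]
    gene_body = integrate.gene_body_mask(annotation)
    if len(repro):
        chip_res = integrate.chip_at_eclip(chip_signal, repro, gene_body)
        results["chip_at_eclip_p"] = chip_res["p"]
    eclip_iv = (
        [(int(r.start), int(r.end)) for r in repro.itertuples()] if len(repro) else []
    )
    chip_iv = [(int(r.start), int(r.end)) for r in chip_peaks.itertuples()]
    results["jaccard_promoter"] = integrate.jaccard_index(
        eclip_iv, chip_iv, annotation.length, integrate.promoter_mask(annotation)
    )
    results["n_reproducible_peaks"] = int(len(repro))
    results["n_significant_events"] = int(
        len(groups["included"]) + len(groups["excluded"])
    )
    with open(out / "integration.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)

    _write_manifest(out, config)
    return out


def _write_manifest(out: Path, config: RunConfig) -> None:
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    digests = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": digests,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
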