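"""Simulated knockdown outputs: a skipped-exon table and a gene table.

Skipped exons are drawn from multi-exon protein-coding genes.  Control
inclusion levels follow a Beta(2, 2) (the generator's choice; the shape is
configurable).  Null events get p ~ Uniform(0, 1) and a small symmetric
dpsi jitter; planted events get the planted dpsi and a p-value drawn from
a Beta(0.05, 1) rescaled into (0, 1e-4), so a planted event always clears
the downstream p, FDR and |dpsi| thresholds by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..annotation import Annotation
from ..splicemaps import EVENT_COLUMNS
from .truth import BindingTruth

PLANTED_P_SCALE = 1e-4


def _candidate_exons(annotation: Annotation) -> list[tuple]:
    out = []
    for g in annotation.genes:
        if g.gene_type != "protein_coding":
            continue
        t = g.transcripts[0]
        for i in range(1, len(t.exons) - 1):
            out.append((g, t, i))
    return out


def simulate_kd_tables(
    annotation: Annotation,
    truth: BindingTruth,
    n_events: int,
    seed: int = 0,
    psi_shape: tuple[float, float] = (2.0, 2.0),
    cell: str = "cellA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (splicing event table, gene expression table)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = _candidate_exons(annotation)
    if not candidates:
        raise ValueError("annotation has no internal exons to build events from")
    idx = rng.choice(len(candidates), size=n_events, replace=n_events > len(candidates))
    rows = []
    for j, ci in enumerate(idx):
        g, t, i = candidates[ci]
        exon = t.exons[i]
        up, down = t.exons[i - 1], t.exons[i + 1]
        if g.strand == "-":
            up, down = down, up
        key = (g.gene_id, i)
        planted = truth.regulation.get(key)
        psi_c = float(rng.beta(*psi_shape))
        if planted is not None:
            dpsi = planted
            psi_c = float(np.clip(psi_c, max(0.0, -dpsi), min(1.0, 1.0 - dpsi)))
            psi_k = float(np.clip(psi_c + dpsi, 0.0, 1.0))
            p = float(rng.beta(0.05, 1.0)) * PLANTED_P_SCALE
        else:
            dpsi = float(rng.normal(0.0, 0.01))
            psi_k = float(np.clip(psi_c + dpsi, 0.0, 1.0))
            p = float(rng.uniform())
        rows.append(
            {
                "event_id": f"SE_{j:05d}",
                "event_type": "SE",
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "exon_start": exon[0],
                "exon_end": exon[1],
                "upstream_es": up[0],
                "upstream_ee": up[1],
                "downstream_es": down[0],
                "downstream_ee": down[1],
                "psi_control": psi_c,
                "psi_kd": psi_k,
                "dpsi": psi_k - psi_c,
                "pvalue": p,
            }
        )
    events = pd.DataFrame(rows)
    events["fdr"] = stats.false_discovery_control(events["pvalue"])
    events = events[EVENT_COLUMNS]

    grows = []
    for g in annotation.genes:
        lfc_planted = truth.de_genes.get(g.gene_id)
        if lfc_planted is not None:
            lfc = lfc_planted
            p = float(rng.beta(0.05, 1.0)) * PLANTED_P_SCALE
        else:
            lfc = float(rng.normal(0.0, 0.1))
            p = float(rng.uniform())
        grows.append(
            {
                "gene_id": g.gene_id,
                "tpm_cellA": g.tpm.get("cellA", 0.0),
                "tpm_cellB": g.tpm.get("cellB", 0.0),
                "log2fc": lfc,
                "pvalue": p,
            }
        )
    genes = pd.DataFrame(grows)
    genes["padj"] = stats.false_discovery_control(genes["pvalue"])
    return events, genes
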