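"""Planted ground truth shared by the generators and the recovery tests."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class BindingTruth:
    """Everything the generators plant and the estimators should recover.

    enriched_elements
        (start, end, fold) genomic intervals where IP sampling density is
        multiplied by ``fold`` (lambda >= 1).
    family_weights
        repeat family id -> IP selection weight (>= 1).
    motif / selection
        RBNS consensus and per-occurrence selection factor s (>= 1).
    regulation
        event key (gene_id, exon index) -> planted delta-psi in [-1, 1].
    de_genes
        gene_id -> planted log2 fold-change upon knockdown.
    """

    enriched_elements: list[tuple[int, int, float]] = field(default_factory=list)
    family_weights: dict[str, float] = field(default_factory=dict)
    motif: str = ""
    selection: float = 1.0
    regulation: dict[tuple[str, int], float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, e, lam in self.enriched_elements:
            if lam < 1:
                raise ValueError(f"planted fold {lam} < 1 at [{s},{e})")
            if not s < e:
                raise ValueError(f"empty planted element [{s},{e})")
        for fam, w in self.family_weights.items():
            if w < 1:
                raise ValueError(f"family weight {w} < 1 for {fam}")
        if self.selection < 1:
            raise ValueError("selection factor s must be >= 1")
        for key, dpsi in self.regulation.items():
            if not -1 <= dpsi <= 1:
                raise ValueError(f"delta-psi {dpsi} outside [-1, 1] for {key}")
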