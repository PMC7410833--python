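"""Run configuration: every stage threshold with its standard default.

Defaults are the analysis cutoffs used throughout: reproducible peaks at
fold >= 8 and p <= 0.001, region-level significance at fold >= 4 and
p <= 1e-5, RBNS logo Z >= 3 and eCLIP logo Z >= 2.8, |dpsi| > 0.05 with a
native-psi band of 0.05-0.95, 1,000 native-event samplings and 100
odds-ratio resampling rounds.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # inputs / outputs
    output_dir: str = "atlas_run"
    blacklist_path: str | None = None
    seed: int = 0

    # synthetic-data scale
    n_genes: int = 30
    n_repeat_families: int = 4
    eclip_depth: int = 20000
    dup_rate: float = 0.1
    rbns_reads: int = 20000
    rbns_read_len: int = 20
    n_events: int = 300
    chip_peaks: int = 200

    # planted truth
    planted_fold: float = 16.0
    rbns_motif: str = "UGCAUG"
    rbns_selection: float = 10.0
    promoter_bias: float = 5.0

    # thresholds (standard defaults)
    peak_min_fold: float = 8.0
    peak_max_p: float = 1e-3
    idr_threshold: float = 0.01
    region_min_fold: float = 4.0
    region_max_p: float = 1e-5
    rbns_z_threshold: float = 3.0
    eclip_z_threshold: float = 2.8
    min_dpsi: float = 0.05
    native_psi_band: tuple[float, float] = (0.05, 0.95)
    n_samplings: int = 1000
    resampling_rounds: int = 100

    # splicing-map geometry
    exonic_window: int = 50
    intronic_window: int = 300

    def to_dict(self) -> dict:
        d = asdict(self)
        d["native_psi_band"] = list(self.native_psi_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "native_psi_band" in d:
            d["native_psi_band"] = tuple(d["native_psi_band"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
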