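"""Run configuration: every tunable threshold in one auditable place.

Defaults reproduce the standard assay conditions and literature
cutoffs; nothing at a call site hard-codes them, so the points where
published schemes disagree (the "mensch" Pe cutoff, the IC50 potency
cutoff, the selectivity-index convention) remain visible and
overridable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pampa import MENSCH_DEFAULT_CUTOFF_PE, PampaGeometry

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # PAMPA plate geometry (cm^2, cm^3, s)
    filter_area_cm2: float = 0.24
    donor_volume_cm3: float = 0.15
    acceptor_volume_cm3: float = 0.18
    incubation_time_s: float = 14400.0
    steady_state_lag_s: float = 240.0
    # classification
    mensch_cutoff_pe: float = MENSCH_DEFAULT_CUTOFF_PE
    # chemical space
    si_convention: str = "A_over_B"
    ic50_cutoff_nM: float = 10_000.0
    k_values: tuple[int, ...] = (5, 10)
    ed_radius: float = 1.0
    # partitioning
    unionized_threshold: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"

    def geometry(self) -> PampaGeometry:
        return PampaGeometry(
            A=self.filter_area_cm2,
            V_D=self.donor_volume_cm3,
            V_A=self.acceptor_volume_cm3,
            t=self.incubation_time_s,
            tau_ss=self.steady_state_lag_s,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_values"] = list(self.k_values)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_values" in d:
            d = {**d, "k_values": tuple(d["k_values"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        """Short digest of the canonical JSON form, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
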