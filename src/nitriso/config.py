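"""Analysis configuration: endmembers, thresholds, and reporting rules.

A flat key-value YAML file maps 1:1 onto :class:`AnalysisConfig`; every
field has a literature- or study-anchored default so ``AnalysisConfig()``
reproduces the standard analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .mixing import ATM_CAP_DELTA17O, ATM_CAP_DELTA17O_CONSERVATIVE

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the end-to-end analysis.

    ``si_caoh_um``/``si_mghco3_um`` are placeholders with no defaults:
    conservative-tracer mixing percentages require user-supplied
    endmember ∑Si concentrations (the underlying reaction-path model is
    not packaged).  ``prefer_reported_anomaly`` controls whether a
    published Δ¹⁷O column, when present, feeds the apportionment instead
    of the anomaly recomputed from deltas (published tables are computed
    from unrounded raw deltas, so the reported value is authoritative
    when reproducing them).
    """

    cap_delta17o_method: str = "linear"
    cap_delta17o_atm: float = ATM_CAP_DELTA17O
    cap_delta17o_atm_conservative: float = ATM_CAP_DELTA17O_CONSERVATIVE
    d18o_atm: float = 53.7
    d15n_atm: float = -2.2
    d18o_nitrification: float = -0.4
    prefer_reported_anomaly: bool = True
    reductase_tolerance: float = 0.15
    pool_equivalence_k: float = 2.0
    regression: str = "ols"
    rayleigh_group_by: str = "fluid_type"
    rayleigh_min_n: int = 3
    si_caoh_um: Optional[float] = None
    si_mghco3_um: Optional[float] = None
    blank_delta_permil: float = 0.0
    blank_nmol: float = 0.0
    report_decimals_delta: int = 1
    report_decimals_fraction: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.cap_delta17o_method not in ("linear", "log"):
            raise ValueError("cap_delta17o_method must be 'linear' or 'log'")
        if self.cap_delta17o_atm <= 0:
            raise ValueError("cap_delta17o_atm must be positive")
        if self.cap_delta17o_atm_conservative < self.cap_delta17o_atm:
            raise ValueError(
                "conservative endmember anomaly must be >= the central value"
            )
        if self.regression not in ("ols", "major_axis"):
            raise ValueError("regression must be 'ols' or 'major_axis'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
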