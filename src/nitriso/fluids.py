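"""Per-well samples, fluid reaction-history classification, tracer mixing.

Ophiolite groundwaters fall on a reaction-progress continuum: shallow
Mg²⁺-HCO₃⁻ fluids (alkaline, open to atmospheric CO₂, short residence
times) grade into deep Ca²⁺-OH⁻ fluids (hyperalkaline, extensively
reacted, closed system).  pH is the primary discriminant; dissolved ∑Si
serves as a conservative tracer of mixing between the two endmembers
because it is far more sensitive to mixing than pH.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional

from .isotopes import IsotopeComposition

log = logging.getLogger(__name__)

__all__ = ["FluidSample", "classify_fluid_type", "si_mixing_fraction", "borehole_of"]

LITHOLOGIES = ("peridotite", "gabbro", "alluvium")
FLUID_TYPES = ("MgHCO3", "CaOH", "gabbro", "transitional", "rainwater")

# pH band separating the two peridotite-hosted fluid families.  Sampled
# fluids span 8.3-9.2 (Mg-HCO3) and 10-11.4 (Ca-OH); the 9.6-10 band is
# labelled transitional so classification is total over [0, 14].
PH_MGHCO3_MAX = 9.6
PH_CAOH_MIN = 10.0


def classify_fluid_type(
    ph: float,
    lithology: Optional[str] = None,
    mg: Optional[float] = None,
    ca: Optional[float] = None,
) -> str:
    """Classify a sample's reaction history from pH and lithology.

    Gabbro-hosted fluids are reported as their own class regardless of
    chemistry.  For peridotite/alluvium: pH < 9.6 → ``MgHCO3``,
    pH ≥ 10 → ``CaOH``, in between → ``transitional``.  When ∑Mg and ∑Ca
    (mM) are supplied, a cation-dominance disagreement with the pH call
    is logged as a warning but pH controls.
    """
    if math.isnan(ph) or not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    if lithology is not None and lithology not in LITHOLOGIES:
        raise ValueError(f"unknown lithology: {lithology!r}")
    if lithology == "gabbro":
        return "gabbro"
    if ph < PH_MGHCO3_MAX:
        label = "MgHCO3"
    elif ph >= PH_CAOH_MIN:
        label = "CaOH"
    else:
        label = "transitional"
    if mg is not None and ca is not None:
        dominant = "CaOH" if ca > mg else "MgHCO3"
        if label in ("MgHCO3", "CaOH") and dominant != label:
            log.warning(
                "cation dominance (Ca=%.3g, Mg=%.3g mM) disagrees with pH-based "
                "class %s; pH controls", ca, mg, label,
            )
    return label


def si_mixing_fraction(
    si_sample: float, si_caoh_end: float, si_mghco3_end: float
) -> float:
    """Fraction of the Mg-HCO₃ endmember in a sample, from conservative ∑Si.

    Affine in ``si_sample`` between the two endmember concentrations
    (μM); values outside [0, 1] are clipped with a logged warning since
    real samples can exceed endmember assumptions.
    """
    if si_caoh_end == si_mghco3_end:
        raise ValueError("endmember Si concentrations must be distinct")
    f = (si_sample - si_caoh_end) / (si_mghco3_end - si_caoh_end)
    if f < 0.0 or f > 1.0:
        clipped = min(max(f, 0.0), 1.0)
        log.warning(
            "Si mixing fraction %.4f outside [0, 1]; clipped to %.1f "
            "(sample exceeds endmember assumptions)", f, clipped,
        )
        return clipped
    return f


_INTERVAL_SUFFIX = re.compile(r"_\d+(?:_\d+)?m$")


def borehole_of(sample_id: str) -> str:
    """Borehole name with any packed-interval suffix stripped.

    ``BA1A_100_400m`` and ``BA1A_55_66m`` are discrete depth intervals of
    borehole BA1A sampled with a packer system.
    """
    return _INTERVAL_SUFFIX.sub("", sample_id)


@dataclass
class FluidSample:
    """One well/year groundwater record.

    Concentrations: ∑Si in μM; ∑Mg, ∑Ca, ∑CO₂ in mM; N species in μM.
    ``nred`` is total reduced N (includes ∑NH₃), measured by mass balance
    after persulfate oxidation.  ``fluid_type`` is derived from pH and
    lithology when not supplied.
    """

    well: str
    year: int
    lithology: Optional[str] = None
    ph: Optional[float] = None
    eh_mv: Optional[float] = None
    si_um: Optional[float] = None
    mg_mm: Optional[float] = None
    ca_mm: Optional[float] = None
    co2_mm: Optional[float] = None
    no3_um: Optional[float] = None
    no2_um: Optional[float] = None
    nh3_um: Optional[float] = None
    nh3_sd_um: Optional[float] = None
    nred_um: Optional[float] = None
    nred_sd_um: Optional[float] = None
    iso_no3: Optional[IsotopeComposition] = None
    iso_no2: Optional[IsotopeComposition] = None
    iso_nred: Optional[IsotopeComposition] = None
    fluid_type: Optional[str] = field(default=None)

    def __post_init__(self):
        for name in ("si_um", "mg_mm", "ca_mm", "co2_mm",
                     "no3_um", "no2_um", "nh3_um", "nred_um"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.ph is not None and not math.isnan(self.ph):
            if not (0.0 <= self.ph <= 14.0):
                raise ValueError(f"pH must lie in [0, 14], got {self.ph}")
        if self.fluid_type is None and self.ph is not None and not math.isnan(self.ph):
            self.fluid_type = classify_fluid_type(self.ph, self.lithology)
        if self.fluid_type is not None and self.fluid_type not in FLUID_TYPES:
            raise ValueError(f"unknown fluid type: {self.fluid_type!r}")
        # reduced N should contain the ammonia pool within uncertainty
        if (
            self.nred_um is not None and self.nh3_um is not None
            and not math.isnan(self.nred_um) and not math.isnan(self.nh3_um)
        ):
            def _sd(v):
                return 0.0 if v is None or math.isnan(v) else v
            sd = math.hypot(_sd(self.nred_sd_um), _sd(self.nh3_sd_um))
            if self.nred_um < self.nh3_um - 2.0 * sd:
                log.warning(
                    "%s %s: N_red (%.1f uM) below ammonia pool (%.1f uM) by more "
                    "than 2 sigma", self.well, self.year, self.nred_um, self.nh3_um,
                )
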