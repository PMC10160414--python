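"""Two-endmember nitrate source apportionment from Δ¹⁷O.

Groundwater nitrate in arid-zone aquifers is a mixture of atmospheric
deposition (carrying a large mass-independent Δ¹⁷O anomaly inherited
from ozone chemistry) and nitrate produced in situ by nitrification
(mass-dependent, Δ¹⁷O = 0).  Because biological turnover fractionates
mass-dependently, Δ¹⁷O is conserved through reaction and the atmospheric
fraction follows from a simple mass balance:

    Δ¹⁷O_mixed = f_atm · Δ¹⁷O_atm + (1 − f_atm) · Δ¹⁷O_biogeo
    f_atm      = Δ¹⁷O_mixed / Δ¹⁷O_atm          (Δ¹⁷O_biogeo = 0)

The measured rainwater anomaly (16.8 ‰) is the default atmospheric
endmember; because a single rain event may undersample the ~15 ‰
seasonal fluctuation of atmospheric Δ¹⁷O, a conservative bound on f_atm
is also computed with an inflated endmember (default 31.8 ‰).  The
bound is a bound, not an uncertainty interval.

Once f_atm is known, the δ¹⁸O of the biogeochemical (nitrification ±
reduction) endmember is recovered by inverting the same mass balance in
δ¹⁸O space.  Mixing arithmetic is done in delta space for consistency
with the f_atm equations; at these magnitudes the error relative to
ratio-space mixing is ≤ 0.05 ‰.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .isotopes import MASS_DEPENDENT_LAMBDA, IsotopeComposition, cap_delta17o

log = logging.getLogger(__name__)

__all__ = [
    "Endmember",
    "MixingResult",
    "atmospheric_fraction",
    "conservative_bound",
    "biogeo_endmember_d18o",
    "mixing_curve",
    "ATM_CAP_DELTA17O",
    "ATM_CAP_DELTA17O_CONSERVATIVE",
    "ATMOSPHERIC_ENDMEMBER",
    "NITRIFICATION_ENDMEMBER",
]

#: Measured rainwater Δ¹⁷O, the central atmospheric endmember (‰).
ATM_CAP_DELTA17O = 16.8
#: Inflated endmember (+15 ‰) for the conservative lower bound on f_atm.
ATM_CAP_DELTA17O_CONSERVATIVE = 31.8


@dataclass(frozen=True)
class Endmember:
    """A named source pool with fixed isotope composition.

    A declared biogeochemical endmember must carry no mass-independent
    anomaly (biological processes fractionate mass-dependently).
    """

    name: str
    iso: IsotopeComposition
    no3_um: Optional[float] = None
    biogeochemical: bool = False

    def __post_init__(self):
        if self.biogeochemical and self.iso.cap_delta17o is not None:
            if abs(self.iso.cap_delta17o) > 1e-9:
                raise ValueError(
                    f"biogeochemical endmember {self.name!r} must have "
                    f"cap_delta17o = 0, got {self.iso.cap_delta17o}"
                )


def _d17o_from_cap(cap: float, d18o: float) -> float:
    # linear-frame delta17O consistent with a prescribed anomaly
    return cap + MASS_DEPENDENT_LAMBDA * d18o


#: Rainwater nitrate endmember (δ¹⁸O 53.7 ‰, Δ¹⁷O 16.8 ‰, δ¹⁵N −2.2 ‰, 252.2 μM).
ATMOSPHERIC_ENDMEMBER = Endmember(
    "atmospheric",
    IsotopeComposition(
        delta15n=-2.2,
        delta18o=53.7,
        delta17o=_d17o_from_cap(ATM_CAP_DELTA17O, 53.7),
    ),
    no3_um=252.2,
)

#: Nitrification endmember: δ¹⁸O of ambient aquifer water (−0.4 ‰), Δ¹⁷O 0.
NITRIFICATION_ENDMEMBER = Endmember(
    "nitrification",
    IsotopeComposition(
        delta18o=-0.4,
        delta17o=_d17o_from_cap(0.0, -0.4),
    ),
    biogeochemical=True,
)


@dataclass(frozen=True)
class MixingResult:
    """Per-sample source apportionment of the nitrate pool."""

    f_atm: float
    f_atm_conservative: float
    f_biogeo: float
    d18o_biogeo: Optional[float] = None

    def __post_init__(self):
        if abs(self.f_atm + self.f_biogeo - 1.0) > 1e-12:
            raise ValueError("f_atm + f_biogeo must equal 1")


def atmospheric_fraction(
    cap_delta17o_mixed: float, cap_delta17o_atm: float = ATM_CAP_DELTA17O
) -> float:
    """Fraction of the nitrate pool of atmospheric origin.

    The quotient Δ¹⁷O_mixed / Δ¹⁷O_atm, clipped to [0, 1] (analytical
    noise can push small anomalies slightly negative); clipping is
    logged.
    """
    if not cap_delta17o_atm > 0:
        raise ValueError("atmospheric endmember cap_delta17o must be positive")
    f = cap_delta17o_mixed / cap_delta17o_atm
    if f < 0.0 or f > 1.0:
        clipped = min(max(f, 0.0), 1.0)
        log.warning("f_atm %.4f outside [0, 1]; clipped to %.1f", f, clipped)
        return clipped
    return f


def conservative_bound(
    cap_delta17o_mixed: float,
    cap_delta17o_atm_upper: float = ATM_CAP_DELTA17O_CONSERVATIVE,
) -> float:
    """Lower bound on f_atm computed with the inflated atmospheric endmember."""
    return atmospheric_fraction(cap_delta17o_mixed, cap_delta17o_atm_upper)


def biogeo_endmember_d18o(
    d18o_mixed: float, f_atm: float, d18o_atm: float = 53.7
) -> float:
    """δ¹⁸O of the biogeochemical nitrate endmember, by mass balance.

    Inverts δ¹⁸O_mixed = f_atm·δ¹⁸O_atm + (1 − f_atm)·δ¹⁸O_biogeo.
    Undefined at f_atm = 1 (no biogeochemical nitrate to characterize).
    """
    if f_atm == 1.0:
        raise ValueError("f_atm = 1: biogeochemical endmember is undefined")
    if not (0.0 <= f_atm < 1.0):
        raise ValueError(f"f_atm must lie in [0, 1), got {f_atm}")
    return (d18o_mixed - f_atm * d18o_atm) / (1.0 - f_atm)


def mixing_curve(
    end_atm: Endmember = ATMOSPHERIC_ENDMEMBER,
    end_biogeo: Endmember = NITRIFICATION_ENDMEMBER,
    f_grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 21)),
) -> pd.DataFrame:
    """Theoretical (δ¹⁸O, Δ¹⁷O) mixing line between two endmembers.

    ``f_grid`` is the fraction of atmospheric endmember fluid.  With
    equal or unspecified endmember nitrate concentrations both δ¹⁸O and
    Δ¹⁷O are affine in f; with differing concentrations the isotope mix
    is mole-weighted.

    Returns a frame with columns ``f``, ``d18o``, ``cap_delta17o``.
    """
    f = np.asarray(list(f_grid), dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f_grid values must lie in [0, 1]")
    c_atm = end_atm.no3_um
    c_bio = end_biogeo.no3_um
    if c_atm is not None and c_bio is not None and c_atm != c_bio:
        moles_atm = f * c_atm
        moles_bio = (1.0 - f) * c_bio
        w = np.divide(
            moles_atm,
            moles_atm + moles_bio,
            out=np.zeros_like(f),
            where=(moles_atm + moles_bio) > 0,
        )
    else:
        w = f
    d18o = w * end_atm.iso.delta18o + (1.0 - w) * end_biogeo.iso.delta18o
    d17o = w * end_atm.iso.delta17o + (1.0 - w) * end_biogeo.iso.delta17o
    cap = cap_delta17o(d17o, d18o, method="linear")
    return pd.DataFrame({"f": f, "d18o": d18o, "cap_delta17o": cap})
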