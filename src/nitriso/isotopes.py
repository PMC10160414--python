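"""Delta-notation arithmetic and the mass-independent oxygen anomaly Δ¹⁷O.

Stable isotope abundances are reported in delta notation: the per-mil
deviation of an isotope ratio from an international reference scale (air
for ¹⁵N/¹⁴N, VSMOW for ¹⁸O/¹⁶O and ¹⁷O/¹⁶O),

    δ = (R_sample / R_reference − 1) · 1000  [‰].

Mass-dependent fractionation ties δ¹⁷O to δ¹⁸O with a scaling of ≈0.52;
the residual anomaly Δ¹⁷O quantifies mass-independent enrichment (e.g.
ozone chemistry imprinted on atmospheric nitrate).  Two reference forms
are in common use:

  logarithmic : Δ¹⁷O = [ln(1 + δ¹⁷O/1000) − λ·ln(1 + δ¹⁸O/1000)]·1000
  linear      : Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O

with λ = 0.52.  Both are exposed; ``linear`` is the package default and
the method in use is always recorded next to the value.  For |δ| ≤ 60 ‰
the two forms differ by < 0.35 ‰.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np

__all__ = [
    "MASS_DEPENDENT_LAMBDA",
    "IsotopeComposition",
    "delta_from_ratio",
    "ratio_from_delta",
    "cap_delta17o",
    "round_half_up",
]

#: Mass-dependent δ¹⁷O/δ¹⁸O scaling exponent (single source of truth).
MASS_DEPENDENT_LAMBDA = 0.52

_DELTA_FLOOR = -1000.0  # delta of -1000 ‰ implies a zero isotope ratio


def _is_absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def delta_from_ratio(r_sample: float, r_reference: float) -> float:
    """Per-mil delta value of ``r_sample`` relative to ``r_reference``.

    Both ratios must be strictly positive.  Inverse of
    :func:`ratio_from_delta`.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_reference = np.asarray(r_reference, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_reference <= 0):
        raise ValueError("isotope ratios must be strictly positive")
    out = (r_sample / r_reference - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def ratio_from_delta(delta: float, r_reference: float) -> float:
    """Isotope ratio implied by a per-mil ``delta`` on reference ``r_reference``."""
    delta = np.asarray(delta, dtype=float)
    r_reference = np.asarray(r_reference, dtype=float)
    if np.any(delta <= _DELTA_FLOOR):
        raise ValueError("delta must exceed -1000 permil (ratios are positive)")
    if np.any(r_reference <= 0):
        raise ValueError("reference ratio must be strictly positive")
    out = r_reference * (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


def cap_delta17o(
    delta17o: Optional[float],
    delta18o: Optional[float],
    method: str = "linear",
    lambda_: float = MASS_DEPENDENT_LAMBDA,
) -> Optional[float]:
    """Mass-independent ¹⁷O anomaly Δ¹⁷O in ‰.

    Parameters
    ----------
    delta17o, delta18o
        δ¹⁷O and δ¹⁸O vs VSMOW in ‰.  If either is absent (``None`` or
        NaN) the result is ``None`` — never a silent zero.
    method
        ``"linear"`` (default): δ¹⁷O − λ·δ¹⁸O.
        ``"log"``: [ln(1+δ¹⁷O/1000) − λ·ln(1+δ¹⁸O/1000)]·1000.
    lambda_
        Mass-dependent scaling exponent (default 0.52).

    A purely mass-dependent composition returns 0 in the frame of the
    chosen method.
    """
    if method not in ("linear", "log"):
        raise ValueError(f"unknown cap_delta17o method: {method!r}")
    if _is_absent(delta17o) or _is_absent(delta18o):
        return None
    d17 = np.asarray(delta17o, dtype=float)
    d18 = np.asarray(delta18o, dtype=float)
    if np.any(d17 <= _DELTA_FLOOR) or np.any(d18 <= _DELTA_FLOOR):
        raise ValueError("delta values must exceed -1000 permil")
    if method == "linear":
        out = d17 - lambda_ * d18
    else:
        out = (np.log1p(d17 / 1000.0) - lambda_ * np.log1p(d18 / 1000.0)) * 1000.0
    return float(out) if out.ndim == 0 else out


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed isotope tables do.

    Values are carried at full precision internally; this is applied only
    at report/serialization time.
    """
    if _is_absent(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IsotopeComposition:
    """Isotope deltas of one N pool with 1σ uncertainties, all in ‰.

    δ¹⁵N is vs air; δ¹⁷O/δ¹⁸O are vs VSMOW.  Absent values are ``None``
    (first-class missing, never sentinel numbers).  ``cap_delta17o`` is
    derived from δ¹⁷O and δ¹⁸O with the recorded method and is ``None``
    whenever either delta is absent.
    """

    delta15n: Optional[float] = None
    delta18o: Optional[float] = None
    delta17o: Optional[float] = None
    sd15n: Optional[float] = None
    sd18o: Optional[float] = None
    sd17o: Optional[float] = None
    cap_delta17o_method: str = "linear"
    cap_delta17o: Optional[float] = field(init=False, default=None)

    def __post_init__(self):
        for name in ("delta15n", "delta18o", "delta17o"):
            v = getattr(self, name)
            if _is_absent(v):
                object.__setattr__(self, name, None)
            elif v <= _DELTA_FLOOR:
                raise ValueError(f"{name} must exceed -1000 permil, got {v}")
        for name in ("sd15n", "sd18o", "sd17o"):
            v = getattr(self, name)
            if _is_absent(v):
                object.__setattr__(self, name, None)
            elif v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        object.__setattr__(
            self,
            "cap_delta17o",
            cap_delta17o(self.delta17o, self.delta18o, self.cap_delta17o_method),
        )
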