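"""Rayleigh distillation of nitrate and dual N-O fractionation fitting.

Closed-system (Rayleigh) consumption of a substrate pool with a kinetic
isotope effect ε (‰, negative for normal discrimination) leaves the
residual pool enriched:

    exact       : δ = (1000 + δ₀) · f^(ε/1000) − 1000
    approximate : δ = δ₀ + ε · ln f

with f the fraction of substrate remaining.  Regressing measured δ on
ln(C/C₀) therefore estimates ε as the slope and δ₀ (the initial-pool
composition) as the intercept.

Nitrate reduction fractionates N and O jointly; the slope of δ¹⁸O vs
δ¹⁵N in the residual pool (the ¹⁸ε/¹⁵ε proportionality) is diagnostic
of the reductase: membrane-bound Nar imparts ≈0.91, periplasmic Nap
≈0.55.  Literature ¹⁵ε ranges are Nar −6.6 to −31.6 ‰ and Nap −11.4 to
−39.8 ‰.

Caveat: an aquifer resupplied by nitrification or diffusive mixing
violates the closed-system assumption; fitted ε are then apparent
(under-)estimates.  This caveat is attached to every report the
pipeline emits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "RayleighFit",
    "rayleigh_forward",
    "fit_epsilon",
    "dual_isotope_proportionality",
    "classify_reductase",
    "epsilon_in_literature_range",
    "fit_rayleigh",
    "NAR_PROPORTIONALITY",
    "NAP_PROPORTIONALITY",
    "EPSILON15_LITERATURE_RANGES",
    "RAYLEIGH_CAVEAT",
]

NAR_PROPORTIONALITY = 0.91
NAP_PROPORTIONALITY = 0.55

#: Literature ¹⁵ε ranges (‰, inclusive) for dissimilatory nitrate reductases.
EPSILON15_LITERATURE_RANGES = {
    "Nar": (-31.6, -6.6),
    "Nap": (-39.8, -11.4),
}

RAYLEIGH_CAVEAT = (
    "Rayleigh fits assume a closed system; resupply of nitrate by "
    "nitrification or diffusive mixing biases fitted epsilon toward zero."
)


def rayleigh_forward(
    delta0: float, epsilon: float, f_remaining: float, form: str = "exact"
) -> float:
    """Residual-pool delta after Rayleigh consumption to fraction ``f_remaining``.

    ``epsilon`` < 0 denotes a normal kinetic isotope effect, under which
    the residual pool strictly enriches as f decreases.  f must lie in
    (0, 1]: a fully consumed pool has no residual composition.
    """
    if form not in ("exact", "approximate"):
        raise ValueError(f"unknown Rayleigh form: {form!r}")
    f = np.asarray(f_remaining, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("f_remaining must lie in (0, 1]")
    delta0 = np.asarray(delta0, dtype=float)
    if form == "exact":
        out = (1000.0 + delta0) * f ** (epsilon / 1000.0) - 1000.0
    else:
        out = delta0 + epsilon * np.log(f)
    return float(out) if out.ndim == 0 else out


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    if len(x) < 3:
        raise ValueError("at least 3 paired observations are required")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the regressor; fit is degenerate")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_epsilon(
    concentrations: Sequence[float],
    deltas: Sequence[float],
    c0: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Estimate (ε, δ₀, r²) from paired concentration/delta series.

    Ordinary least squares of δ on ln(C/C₀) under the approximate
    Rayleigh form; the slope is ε (negative for a residual-enrichment
    trend) and the intercept the initial-pool δ₀ at f = 1.  ``c0``
    defaults to the maximum observed concentration — the true initial
    pool is rarely known in field data, and the choice shifts only the
    intercept, never the slope.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if c.shape != d.shape:
        raise ValueError("concentration and delta series must align")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if c0 is None:
        c0 = float(np.max(c))
    elif c0 <= 0:
        raise ValueError("c0 must be strictly positive")
    x = np.log(c / c0)
    return _ols(x, d)


def dual_isotope_proportionality(
    delta15_series: Sequence[float],
    delta18_series: Sequence[float],
    method: str = "ols",
) -> Tuple[float, float, float]:
    """Estimate the ¹⁸ε/¹⁵ε proportionality as (slope, intercept, r²).

    ``ols`` regresses δ¹⁸O on δ¹⁵N.  ``major_axis`` fits the principal
    axis of the joint scatter, appropriate when both isotopes carry
    comparable analytical error.
    """
    x = np.asarray(delta15_series, dtype=float)
    y = np.asarray(delta18_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("delta series must align")
    if method == "ols":
        return _ols(x, y)
    if method == "major_axis":
        if len(x) < 3:
            raise ValueError("at least 3 paired observations are required")
        sxx = np.var(x)
        syy = np.var(y)
        sxy = np.cov(x, y, bias=True)[0, 1]
        if sxx == 0 or sxy == 0:
            raise ValueError("degenerate variance; major-axis fit undefined")
        slope = (syy - sxx + math.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
        intercept = float(np.mean(y) - slope * np.mean(x))
        r2 = float(sxy**2 / (sxx * syy)) if syy > 0 else 0.0
        return float(slope), intercept, r2
    raise ValueError(f"unknown regression method: {method!r}")


def classify_reductase(
    proportionality: float,
    nar: float = NAR_PROPORTIONALITY,
    nap: float = NAP_PROPORTIONALITY,
    tolerance: float = 0.15,
) -> str:
    """Label a ¹⁸ε/¹⁵ε slope as Nar-consistent, Nap-consistent, or ambiguous."""
    if not math.isfinite(proportionality):
        raise ValueError("proportionality must be finite")
    near_nar = abs(proportionality - nar) <= tolerance
    near_nap = abs(proportionality - nap) <= tolerance
    if near_nar and not near_nap:
        return "Nar-consistent"
    if near_nap and not near_nar:
        return "Nap-consistent"
    return "ambiguous"


def epsilon_in_literature_range(epsilon15: float, enzyme: str) -> bool:
    """Whether a fitted ¹⁵ε falls in the literature range for ``enzyme`` (inclusive)."""
    if not math.isfinite(epsilon15):
        raise ValueError("epsilon15 must be finite")
    try:
        lo, hi = EPSILON15_LITERATURE_RANGES[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme: {enzyme!r} (expected 'Nar' or 'Nap')")
    return lo <= epsilon15 <= hi


@dataclass(frozen=True)
class RayleighFit:
    """Joint N-O Rayleigh fit for one stratum of samples.

    ``proportionality`` is ε¹⁸/ε¹⁵ from the two single-isotope fits;
    ``r2_dual`` is the diagnostic r² of the direct δ¹⁸O-on-δ¹⁵N
    regression.
    """

    epsilon15: float
    epsilon18: float
    proportionality: float
    intercept15: float
    intercept18: float
    r2_15: float
    r2_18: float
    r2_dual: float
    n: int
    reductase_label: str

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("a reported fit requires n >= 3")
        if self.epsilon15 != 0 and math.isfinite(self.proportionality):
            if abs(self.proportionality - self.epsilon18 / self.epsilon15) > 1e-9:
                raise ValueError("proportionality must equal epsilon18/epsilon15")


def fit_rayleigh(
    concentrations: Sequence[float],
    delta15_series: Sequence[float],
    delta18_series: Sequence[float],
    c0: Optional[float] = None,
    reductase_tolerance: float = 0.15,
) -> RayleighFit:
    """Fit ε¹⁵, ε¹⁸ and their proportionality for one group of samples."""
    e15, b15, r15 = fit_epsilon(concentrations, delta15_series, c0)
    e18, b18, r18 = fit_epsilon(concentrations, delta18_series, c0)
    _, _, r2_dual = dual_isotope_proportionality(delta15_series, delta18_series)
    prop = e18 / e15 if e15 != 0 else math.nan
    label = (
        classify_reductase(prop, tolerance=reductase_tolerance)
        if math.isfinite(prop)
        else "ambiguous"
    )
    return RayleighFit(
        epsilon15=e15,
        epsilon18=e18,
        proportionality=prop,
        intercept15=b15,
        intercept18=b18,
        r2_15=r15,
        r2_18=r18,
        r2_dual=r2_dual,
        n=len(list(concentrations)),
        reductase_label=label,
    )
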