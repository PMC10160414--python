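"""Synthetic aquifer datasets with the isotope systematics the analysis assumes.

The generator emulates the process chain the pipeline inverts: nitrate
enters each synthetic sample as a two-endmember mixture of atmospheric
deposition and nitrification (drawing a per-sample atmospheric fraction),
is then partially consumed by closed-system Rayleigh reduction with a
configurable ¹⁵ε and ¹⁸ε/¹⁵ε proportionality (¹⁷ε mass-dependently tied
to ¹⁸ε), with the consumed N routed to ∑NH₃ by mass conservation, and is
finally observed through Gaussian analytical noise at the stated
per-isotope precisions.  A hidden-truth table (drawn fractions and
pre-noise values) is always emitted alongside the observables, because
parameter recovery is the acceptance surface of the analysis.

pH is emitted as a monotone map of reaction progress (more reduction →
more reacted, higher pH) so the fluid classifier has an input; the map
is a convenience for end-to-end testing, not a speciation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .isotopes import MASS_DEPENDENT_LAMBDA
from .mixing import ATMOSPHERIC_ENDMEMBER, NITRIFICATION_ENDMEMBER, Endmember
from .npools import PoolPair
from .rayleigh import rayleigh_forward

__all__ = [
    "NoiseModel",
    "SimulationParams",
    "generate_aquifer_dataset",
    "generate_rayleigh_series",
    "generate_nitrite_pairs",
]


@dataclass(frozen=True)
class NoiseModel:
    """1σ analytical precisions (‰; concentrations as CV).

    Denitrifier-method precisions for δ¹⁵N and δ¹⁸O; separate, larger
    precisions for the triple-oxygen analyses (thermal decomposition
    route).
    """

    sd_d15n: float = 0.1
    sd_d18o: float = 0.3
    sd_d18o_tripleo: float = 0.84
    sd_d17o: float = 0.64
    conc_cv: float = 0.03

    def __post_init__(self):
        for name in ("sd_d15n", "sd_d18o", "sd_d18o_tripleo", "sd_d17o", "conc_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def zeroed(self) -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic aquifer dataset.

    ``f_atm_range`` (uniform on [0.18, 0.41], the observed groundwater
    range) and ``f_remaining_range`` (log-uniform on [0.05, 1]) collapse
    to constants when low == high.  ``d15n_nitrification`` has no
    field-constrained value (it tracks the ambient ammonia substrate)
    and defaults to the midrange of observed nitrified nitrate.
    """

    n_samples: int = 50
    seed: int = 0
    end_atm: Endmember = ATMOSPHERIC_ENDMEMBER
    end_nit: Endmember = NITRIFICATION_ENDMEMBER
    d15n_nitrification: float = 5.0
    no3_initial_um: float = 140.0
    f_atm_range: Tuple[float, float] = (0.18, 0.41)
    f_remaining_range: Tuple[float, float] = (0.05, 1.0)
    epsilon15: float = -17.5
    proportionality: float = 0.91
    rayleigh_form: str = "exact"
    noise: NoiseModel = field(default_factory=NoiseModel)
    year: int = 2018

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        lo, hi = self.f_atm_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("f_atm_range must satisfy 0 <= low <= high <= 1")
        lo, hi = self.f_remaining_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("f_remaining_range must satisfy 0 < low <= high <= 1")
        if self.no3_initial_um <= 0:
            raise ValueError("no3_initial_um must be positive")
        if self.rayleigh_form not in ("exact", "approximate"):
            raise ValueError("rayleigh_form must be 'exact' or 'approximate'")


def _draw(rng: np.random.Generator, lo: float, hi: float, n: int, log: bool) -> np.ndarray:
    if lo == hi:
        return np.full(n, lo)
    if log:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return rng.uniform(lo, hi, n)


def generate_aquifer_dataset(
    params: SimulationParams,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (observables, hidden truth) for one synthetic aquifer.

    The observables frame follows the pipeline sample schema; the truth
    frame records per-sample f_atm, f_remaining and all pre-noise
    quantities.  Output is fully determined by ``params`` (seed
    included).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_samples

    f_atm = _draw(rng, *p.f_atm_range, n, log=False)
    f_rem = _draw(rng, *p.f_remaining_range, n, log=True)

    atm, nit = p.end_atm.iso, p.end_nit.iso
    d15n_nit = p.d15n_nitrification
    # two-endmember mixing in delta space; mass-dependent delta17O on the
    # nitrification side so the linear anomaly is exactly f_atm * cap_atm
    d15n0 = f_atm * atm.delta15n + (1 - f_atm) * d15n_nit
    d18o0 = f_atm * atm.delta18o + (1 - f_atm) * nit.delta18o
    d17o0 = f_atm * atm.delta17o + (1 - f_atm) * nit.delta17o

    eps15 = p.epsilon15
    eps18 = p.proportionality * eps15
    eps17 = MASS_DEPENDENT_LAMBDA * eps18
    d15n = rayleigh_forward(d15n0, eps15, f_rem, form=p.rayleigh_form)
    d18o = rayleigh_forward(d18o0, eps18, f_rem, form=p.rayleigh_form)
    d17o = rayleigh_forward(d17o0, eps17, f_rem, form=p.rayleigh_form)

    c0 = p.no3_initial_um
    no3 = c0 * f_rem
    nh3 = c0 * (1 - f_rem)  # consumed N routed to ammonia (mass conservation)
    with np.errstate(invalid="ignore", divide="ignore"):
        d15n_nred = np.where(
            nh3 > 0, (c0 * d15n0 - no3 * d15n) / np.where(nh3 > 0, nh3, 1), np.nan
        )

    ph = 8.3 + (11.4 - 8.3) * (1 - f_rem)  # reaction-progress proxy

    nz = p.noise
    obs = pd.DataFrame(
        {
            "well": [f"SYN{i:03d}" for i in range(1, n + 1)],
            "year": p.year,
            "lithology": "peridotite",
            "ph": ph,
            "no3_um": no3 * (1 + nz.conc_cv * rng.standard_normal(n)),
            "no2_um": 0.0,
            "nh3_um": nh3 * (1 + nz.conc_cv * rng.standard_normal(n)),
            "nred_um": nh3 * (1 + nz.conc_cv * rng.standard_normal(n)),
            "d15n_no3_permil": d15n + nz.sd_d15n * rng.standard_normal(n),
            "d18o_no3_permil": d18o + nz.sd_d18o * rng.standard_normal(n),
            "d18o_no3_tripleo_permil": d18o + nz.sd_d18o_tripleo * rng.standard_normal(n),
            "d17o_no3_permil": d17o + nz.sd_d17o * rng.standard_normal(n),
            "d15n_nred_permil": d15n_nred + nz.sd_d15n * rng.standard_normal(n),
        }
    )
    obs["no3_um"] = obs["no3_um"].clip(lower=0.0)
    obs["nh3_um"] = obs["nh3_um"].clip(lower=0.0)
    obs["nred_um"] = obs["nred_um"].clip(lower=0.0)

    truth = pd.DataFrame(
        {
            "well": obs["well"],
            "f_atm": f_atm,
            "f_remaining": f_rem,
            "no3_initial_um": c0,
            "no3_um": no3,
            "nh3_um": nh3,
            "d15n_no3_initial_permil": d15n0,
            "d18o_no3_initial_permil": d18o0,
            "d17o_no3_initial_permil": d17o0,
            "d15n_no3_permil": d15n,
            "d18o_no3_permil": d18o,
            "d17o_no3_permil": d17o,
            "cap_delta17o_permil": d17o - MASS_DEPENDENT_LAMBDA * d18o,
            "d15n_nred_permil": d15n_nred,
            "epsilon15": eps15,
            "epsilon18": eps18,
        }
    )
    return obs, truth


def generate_rayleigh_series(
    delta0: float,
    epsilon: float,
    f_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    c0: float = 100.0,
    form: str = "approximate",
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired (concentration, delta) series along a Rayleigh trajectory.

    Concentrations are c0·f; deltas are the forward model plus Gaussian
    noise of sd ``noise_sd``.  Deterministic under ``seed``.
    """
    f = np.asarray(list(f_grid), dtype=float)
    if f.size == 0:
        raise ValueError("f_grid must not be empty")
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("f_grid values must lie in (0, 1]")
    deltas = rayleigh_forward(delta0, epsilon, f, form=form)
    deltas = np.asarray(deltas, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        deltas = deltas + noise_sd * rng.standard_normal(f.shape)
    return c0 * f, deltas


def generate_nitrite_pairs(
    c_no3: float,
    d_no3: float,
    c_no2: float,
    d_no2: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> PoolPair:
    """Compose a treated/untreated pool pair by mole-weighted mixing.

    Exact inverse of nitrite inference by mass balance at zero noise.
    """
    if c_no3 < 0 or c_no2 < 0:
        raise ValueError("concentrations must be nonnegative")
    c_total = c_no3 + c_no2
    if c_total > 0:
        delta_total = (c_no3 * d_no3 + c_no2 * d_no2) / c_total
    else:
        delta_total = d_no3
    delta_sub = d_no3
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        delta_total += noise_sd * rng.standard_normal()
        delta_sub += noise_sd * rng.standard_normal()
    return PoolPair(
        c_total=c_total, delta_total=delta_total, c_sub=c_no3, delta_sub=delta_sub
    )
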