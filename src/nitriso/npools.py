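"""Mass-balance corrections and ancillary N-pool models.

Covers the bookkeeping around the core apportionment: inference of
nitrite isotopes from paired treated/untreated analyses (selective
nitrite removal with sulfamic acid), correction of persulfate-oxidation
analyses for reagent nitrate blanks, the reduced-N vs ammonia pool
consistency check, and equilibrium-driven enrichment of residual
ammonia during degassing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Set, Tuple

import pandas as pd

from .fluids import borehole_of
from .rayleigh import rayleigh_forward

log = logging.getLogger(__name__)

__all__ = [
    "PoolPair",
    "nitrite_isotopes_by_massbalance",
    "persulfate_blank_correction",
    "nred_is_ammonium",
    "mixed_reduced_n_boreholes",
    "nh3_degassing",
    "NH3_DEGASSING_EPSILON",
]

#: Equilibrium isotope effect (‰) for ∑NH₃ speciation/volatilization/degassing.
NH3_DEGASSING_EPSILON = -42.5


@dataclass(frozen=True)
class PoolPair:
    """A total N pool and the sub-pool remaining after selective removal.

    ``c_total``/``delta_total`` describe the untreated analysis
    (e.g. NO₃⁻ + NO₂⁻); ``c_sub``/``delta_sub`` the treated aliquot
    (NO₃⁻ only, after sulfamic-acid nitrite removal).  Concentrations in
    μM, deltas in ‰; the same pairing applies to δ¹⁵N and δ¹⁸O.
    """

    c_total: float
    delta_total: float
    c_sub: float
    delta_sub: float

    def __post_init__(self):
        if self.c_sub < 0 or self.c_total < self.c_sub:
            raise ValueError("pools must satisfy c_total >= c_sub >= 0")


def nitrite_isotopes_by_massbalance(pair: PoolPair) -> Tuple[float, float]:
    """(concentration, delta) of the removed NO₂⁻ pool, by isotope mass balance.

    c_no2 = c_total − c_sub and
    δ_no2 = (c_total·δ_total − c_sub·δ_sub) / c_no2.  A removed pool
    below 1% of the total is returned with a warning: at that level the
    inferred delta is poorly constrained (removal was only applied above
    1% nitrite in practice).
    """
    c_no2 = pair.c_total - pair.c_sub
    if c_no2 <= 0:
        raise ValueError("no inferable pool: c_total must exceed c_sub")
    if c_no2 < 0.01 * pair.c_total:
        log.warning(
            "removed pool is %.2f%% of total (<1%%); inferred delta is "
            "poorly constrained", 100.0 * c_no2 / pair.c_total,
        )
    delta_no2 = (pair.c_total * pair.delta_total - pair.c_sub * pair.delta_sub) / c_no2
    return c_no2, delta_no2


def persulfate_blank_correction(
    delta_measured: float, n_measured: float, delta_blank: float, n_blank: float
) -> float:
    """Blank-corrected delta of a persulfate-oxidized sample (isotope dilution).

    ``n_measured``/``n_blank`` are analyte amounts (nmol) of the
    measured pool and of the reagent nitrate blank constrained by amino
    acid standards.  Inverts the mole-weighted mixing of sample and
    blank.
    """
    if n_blank < 0:
        raise ValueError("blank amount must be nonnegative")
    if n_measured <= n_blank:
        raise ValueError("blank-dominated analysis: n_measured must exceed n_blank")
    return (delta_measured * n_measured - delta_blank * n_blank) / (
        n_measured - n_blank
    )


def nred_is_ammonium(
    nred: float,
    sd_nred: float,
    nh3: float,
    sd_nh3: float,
    k: float = 2.0,
) -> bool:
    """Whether total reduced N is consistent with being entirely ∑NH₃.

    True iff |N_red − ∑NH₃| ≤ k·sqrt(σ_red² + σ_NH₃²) (default k = 2).
    Samples failing this flag δ¹⁵N_red as a mixed reduced-N pool
    (organic N etc.) rather than a clean ammonia measurement.
    """
    if min(nred, nh3) < 0 or min(sd_nred, sd_nh3) < 0:
        raise ValueError("concentrations and uncertainties must be nonnegative")
    return abs(nred - nh3) <= k * math.hypot(sd_nred, sd_nh3)


def mixed_reduced_n_boreholes(
    table: pd.DataFrame, k: float = 2.0
) -> Set[str]:
    """Boreholes whose reduced-N pool is persistently more than ∑NH₃.

    Applies :func:`nred_is_ammonium` per sample, groups samples by
    borehole (packed-interval suffixes stripped), and flags a borehole
    only when *every* evaluable sample fails: a single discordant year is
    treated as measurement scatter, consistent discordance as evidence of
    a non-ammonia reduced-N component.  Expects the Table-3-style schema
    (``sample``, ``nred_um``, ``nred_sd_um``, ``nh3_um``, ``nh3_sd_um``).
    """
    verdicts: dict[str, list[bool]] = {}
    for _, row in table.iterrows():
        if pd.isna(row["nh3_um"]) or pd.isna(row["nred_um"]):
            continue
        ok = nred_is_ammonium(
            row["nred_um"],
            row["nred_sd_um"] if pd.notna(row["nred_sd_um"]) else 0.0,
            row["nh3_um"],
            row["nh3_sd_um"] if pd.notna(row["nh3_sd_um"]) else 0.0,
            k=k,
        )
        verdicts.setdefault(borehole_of(str(row["sample"])), []).append(ok)
    return {well for well, oks in verdicts.items() if not any(oks)}


def nh3_degassing(
    delta0: float,
    f_remaining: float,
    epsilon_eq: float = NH3_DEGASSING_EPSILON,
    form: str = "exact",
) -> float:
    """δ¹⁵N of residual ∑NH₃ after partial loss by degassing.

    Forward Rayleigh model driven by the equilibrium isotope effect of
    ammonia speciation/volatilization, applied as if kinetic — a
    simplification appropriate for reasoning about residual-pool
    enrichment, not a full air-water exchange model.
    """
    return rayleigh_forward(delta0, epsilon_eq, f_remaining, form=form)
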