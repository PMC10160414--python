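"""End-to-end analysis driver: classify → Δ¹⁷O → f_atm → biogeo δ¹⁸O → Rayleigh.

Each stage is applied per sample row; a failure in one row flags that
row and never aborts the run.  The Rayleigh stage groups rows by a
configurable stratum (fluid type by default) and fits ε¹⁵, ε¹⁸ and
their proportionality per group.  The run is deterministic under a
fixed configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .config import AnalysisConfig
from .fluids import classify_fluid_type
from .isotopes import cap_delta17o, round_half_up
from .mixing import atmospheric_fraction, biogeo_endmember_d18o, conservative_bound
from .rayleigh import RAYLEIGH_CAVEAT, fit_rayleigh

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Per-sample results, per-stratum Rayleigh fits, and a text report."""

    results: pd.DataFrame
    rayleigh: pd.DataFrame
    report: str


def _get(row: pd.Series, col: str):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def run_pipeline(samples: pd.DataFrame, config: Optional[AnalysisConfig] = None) -> PipelineResult:
    """Run the full apportionment/fractionation analysis on a sample frame.

    ``samples`` follows the schema of :func:`nitriso.io.read_samples`.
    Stages: fluid classification (skipped per row without pH when a
    fluid_type is given), anomaly computation, atmospheric-fraction mass
    balance with conservative bound, biogeochemical endmember δ¹⁸O, and
    per-stratum Rayleigh fits.
    """
    cfg = config or AnalysisConfig()
    rows: List[dict] = []
    for _, row in samples.iterrows():
        flags: List[str] = []
        fluid_type = _get(row, "fluid_type")
        ph = _get(row, "ph")
        if fluid_type is None and ph is not None:
            try:
                fluid_type = classify_fluid_type(ph, _get(row, "lithology"))
            except ValueError as exc:
                flags.append(f"classification failed: {exc}")
        elif fluid_type is None:
            flags.append("no pH and no fluid_type; classification skipped")

        # anomaly from the triple-oxygen delta pair (the paired analysis),
        # falling back to the denitrifier-method d18o
        d17o = _get(row, "d17o_no3_permil")
        d18o_pair = _get(row, "d18o_no3_tripleo_permil")
        if d18o_pair is None:
            d18o_pair = _get(row, "d18o_no3_permil")
        cap_computed = (
            cap_delta17o(d17o, d18o_pair, cfg.cap_delta17o_method)
            if d17o is not None and d18o_pair is not None
            else None
        )
        cap_reported = _get(row, "cap_delta17o_permil")
        cap_used = (
            cap_reported
            if (cfg.prefer_reported_anomaly and cap_reported is not None)
            else cap_computed
        )

        f_atm = f_cons = d18o_biogeo = None
        if cap_used is not None:
            try:
                f_atm = atmospheric_fraction(cap_used, cfg.cap_delta17o_atm)
                f_cons = conservative_bound(cap_used, cfg.cap_delta17o_atm_conservative)
            except ValueError as exc:
                flags.append(f"apportionment failed: {exc}")
        if f_atm is not None and d18o_pair is not None:
            if f_atm < 1.0:
                d18o_biogeo = biogeo_endmember_d18o(d18o_pair, f_atm, cfg.d18o_atm)
            else:
                flags.append("f_atm = 1: biogeochemical endmember undefined")

        rows.append(
            {
                "well": row["well"],
                "year": row["year"],
                "fluid_type": fluid_type,
                "cap_delta17o_computed": cap_computed,
                "cap_delta17o_used": cap_used,
                "f_atm": f_atm,
                "f_atm_conservative": f_cons,
                "d18o_biogeo": d18o_biogeo,
                "flags": "; ".join(flags),
            }
        )
    results = pd.DataFrame(rows)

    fits: List[dict] = []
    group_col = cfg.rayleigh_group_by
    if group_col in samples.columns or group_col == "fluid_type":
        grouped = samples.assign(
            _stratum=results["fluid_type"].values
            if group_col == "fluid_type"
            else samples[group_col]
        )
        for stratum, grp in grouped.groupby("_stratum", dropna=True):
            sub = grp.dropna(
                subset=["no3_um", "d15n_no3_permil", "d18o_no3_permil"]
            )
            sub = sub[sub["no3_um"] > 0]
            if len(sub) < cfg.rayleigh_min_n:
                continue
            try:
                fit = fit_rayleigh(
                    sub["no3_um"].to_numpy(),
                    sub["d15n_no3_permil"].to_numpy(),
                    sub["d18o_no3_permil"].to_numpy(),
                    reductase_tolerance=cfg.reductase_tolerance,
                )
            except ValueError as exc:
                log.warning("Rayleigh fit failed for stratum %s: %s", stratum, exc)
                continue
            fits.append(
                {
                    "stratum": stratum,
                    "n": fit.n,
                    "epsilon15": fit.epsilon15,
                    "epsilon18": fit.epsilon18,
                    "proportionality": fit.proportionality,
                    "intercept15": fit.intercept15,
                    "intercept18": fit.intercept18,
                    "r2_15": fit.r2_15,
                    "r2_18": fit.r2_18,
                    "r2_dual": fit.r2_dual,
                    "reductase_label": fit.reductase_label,
                }
            )
    rayleigh_df = pd.DataFrame(
        fits,
        columns=[
            "stratum", "n", "epsilon15", "epsilon18", "proportionality",
            "intercept15", "intercept18", "r2_15", "r2_18", "r2_dual",
            "reductase_label",
        ],
    )

    n_flagged = int((results["flags"] != "").sum())
    lines = [
        "nitriso pipeline report",
        f"samples: {len(results)}  flagged: {n_flagged}",
        f"anomaly method: {cfg.cap_delta17o_method}; "
        f"atmospheric endmember {cfg.cap_delta17o_atm} permil "
        f"(conservative {cfg.cap_delta17o_atm_conservative} permil)",
    ]
    done = results["f_atm"].notna()
    if done.any():
        lo = round_half_up(float(results.loc[done, "f_atm"].min()), cfg.report_decimals_fraction)
        hi = round_half_up(float(results.loc[done, "f_atm"].max()), cfg.report_decimals_fraction)
        lines.append(f"f_atm range: {lo} to {hi} over {int(done.sum())} samples")
    for f in fits:
        lines.append(
            f"stratum {f['stratum']}: n={f['n']} eps15={f['epsilon15']:.2f} "
            f"eps18={f['epsilon18']:.2f} 18e/15e={f['proportionality']:.2f} "
            f"({f['reductase_label']})"
        )
    lines.append(f"caveat: {RAYLEIGH_CAVEAT}")
    for _, r in results[results["flags"] != ""].iterrows():
        lines.append(f"flag {r['well']} {r['year']}: {r['flags']}")

    return PipelineResult(results=results, rayleigh=rayleigh_df, report="\n".join(lines))
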