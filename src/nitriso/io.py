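"""CSV schemas, packaged table fixtures, and sample readers.

The interchange format is plain comma-separated UTF-8 text with a
header row, decimal points, and empty cells for absent values.  Column
names carry unit suffixes: ``_um`` (μM), ``_mm`` (mM), ``_permil`` (‰),
``_mv`` (mV).

Sample schema (``read_samples``):

================================  =============================================
column                            meaning
================================  =============================================
well (mandatory)                  well / sample identifier
year (mandatory)                  sampling year
ph (mandatory; cells may be empty) field pH
lithology                         peridotite | gabbro | alluvium
eh_mv                             oxidation-reduction potential
si_um, mg_mm, ca_mm, co2_mm       major-element chemistry
no3_um, no2_um, nh3_um, nred_um   N-species concentrations (± *_sd_um)
d15n_no3_permil                   δ¹⁵N of nitrate (± *_sd_permil)
d18o_no3_permil                   δ¹⁸O of nitrate, denitrifier analysis
d18o_no3_tripleo_permil           δ¹⁸O of nitrate, triple-oxygen analysis
d17o_no3_permil                   δ¹⁷O of nitrate
cap_delta17o_permil               reported Δ¹⁷O, if published alongside deltas
d15n_nred_permil                  δ¹⁵N of total reduced N
fluid_type                        MgHCO3 | CaOH | gabbro | transitional |
                                  rainwater (overrides classification)
================================  =============================================

The in-study data tables ship as packaged fixtures so the full analysis
runs offline; ``study_samples`` merges them into the sample schema.
"""

from __future__ import annotations

import logging
from importlib import resources


import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["FIXTURE_TABLES", "load_table", "study_samples", "read_samples"]

FIXTURE_TABLES = {
    "wells": "table1_wells.csv",
    "no3_isotopes": "table2_no3_isotopes.csv",
    "reduced_n": "table3_reduced_n.csv",
    "no2_isotopes": "table4_no2_isotopes.csv",
    "n2o": "table5_n2o.csv",
    "triple_oxygen": "table6_triple_oxygen.csv",
    "rock_n": "table7_rock_n.csv",
}

MANDATORY_COLUMNS = ("well", "year", "ph")

KNOWN_COLUMNS = MANDATORY_COLUMNS + (
    "lithology", "eh_mv", "si_um", "mg_mm", "ca_mm", "co2_mm",
    "no3_um", "no3_sd_um", "no2_um", "no2_sd_um",
    "nh3_um", "nh3_sd_um", "nred_um", "nred_sd_um",
    "d15n_no3_permil", "d15n_no3_sd_permil",
    "d18o_no3_permil", "d18o_no3_sd_permil",
    "d18o_no3_tripleo_permil",
    "d17o_no3_permil", "d17o_no3_sd_permil",
    "cap_delta17o_permil", "cap_delta17o_sd_permil",
    "d15n_nred_permil", "d15n_nred_sd_permil",
    "fluid_type",
)

_NUMERIC = [c for c in KNOWN_COLUMNS if c not in ("well", "lithology", "fluid_type")]


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged in-study data table by short name.

    Names: ``wells``, ``no3_isotopes``, ``reduced_n``, ``no2_isotopes``,
    ``n2o``, ``triple_oxygen``, ``rock_n``.
    """
    try:
        fname = FIXTURE_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown table {name!r}; choose from {sorted(FIXTURE_TABLES)}"
        )
    with resources.files("nitriso.data").joinpath(fname).open("r") as fh:
        return pd.read_csv(fh)


def study_samples() -> pd.DataFrame:
    """The in-study samples merged into the pipeline sample schema.

    Joins the nitrate-isotope, reduced-N and triple-oxygen tables on
    (sample, year).  Field pH is not tabulated in the study text, so the
    ``ph`` column is present but empty; fluid types come from the
    published per-sample labels.
    """
    t2 = load_table("no3_isotopes").rename(columns={"sample": "well"})
    t3 = load_table("reduced_n").rename(columns={"sample": "well"})
    t6 = load_table("triple_oxygen").rename(
        columns={
            "sample": "well",
            "d18o_no3_permil": "d18o_no3_tripleo_permil",
            "d18o_no3_sd_permil": "d18o_no3_tripleo_sd_permil",
        }
    )
    df = t2.merge(
        t3[["well", "year", "nred_um", "nred_sd_um", "nh3_um", "nh3_sd_um",
            "d15n_nred_permil", "d15n_nred_sd_permil"]],
        on=["well", "year"],
        how="outer",
    )
    # fluid type for rows only present in the reduced-N table
    ftypes = pd.concat(
        [t2[["well", "year", "fluid_type"]], t3[["well", "year", "fluid_type"]]]
    ).drop_duplicates(["well", "year"])
    df = df.drop(columns=["fluid_type"]).merge(ftypes, on=["well", "year"], how="left")
    df = df.merge(
        t6[["well", "year", "d18o_no3_tripleo_permil", "d17o_no3_permil",
            "d17o_no3_sd_permil", "cap_delta17o_permil"]],
        on=["well", "year"],
        how="left",
    )
    df["ph"] = float("nan")
    return df.sort_values(["well", "year"]).reset_index(drop=True)


def read_samples(path) -> pd.DataFrame:
    """Read a sample CSV into a typed frame with explicit absent values.

    Unknown columns are kept but warned about; missing mandatory columns
    (well, year, ph) raise a schema error; empty cells become NaN
    (explicit absent), and numeric columns are coerced.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"schema error: {path} is empty")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        log.warning("unknown columns ignored by the pipeline: %s", unknown)
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["well"] = df["well"].astype(str)
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a sample frame back to CSV (empty cells for absent values)."""
    df.to_csv(path, index=False)
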