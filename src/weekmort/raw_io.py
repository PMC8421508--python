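"""Readers and writers for the raw weekly input and harmonized output CSVs.

The raw input dialect is one row per weekly death count with nine fields:
population code, sub-area, year, week, sex, lower age bound, age-interval
length, data type (occurrence vs registration) and access level, plus the
death count itself.  Unknown age is encoded by the reserved token ``UNK`` in
the Age column, an open-ended terminal interval by ``+`` in AgeInterval, and
an empty Area means the whole country.

The harmonized output is one row per (country, year, week, sex) with death
counts and person-week rates for the five standard age groups and all ages
combined, followed by the Split / SplitSex / Forecast indicator columns.
Numbers are written at full precision — splitting produces fractional
counts and no rounding is applied anywhere — so write/read round-trips are
lossless.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from weekmort.harmonizer import STANDARD_AGE_GROUPS, age_group_label

__all__ = [
    "FormatError",
    "ValidationError",
    "RAW_FIELDS",
    "UNKNOWN_AGE_TOKEN",
    "OPEN_INTERVAL_TOKEN",
    "read_raw_deaths",
    "write_raw_deaths",
    "stmf_columns",
    "write_stmf_output",
    "read_stmf_output",
]


class FormatError(ValueError):
    """The file does not match the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """The file parses but violates a data invariant (e.g. negative deaths)."""


#: Canonical raw-input field names, in column order.  The mapping from
#: canonical name to the header spelling actually used in a file is
#: configurable via the ``fields`` argument of the reader/writer.
RAW_FIELDS: tuple[str, ...] = (
    "PopName", "Area", "Year", "Week", "Sex", "Age",
    "AgeInterval", "Type", "Access", "Deaths",
)

UNKNOWN_AGE_TOKEN = "UNK"
OPEN_INTERVAL_TOKEN = "+"

_SEX_CODES = {"m": "m", "f": "f", "b": "b",
              "male": "m", "female": "f", "both": "b",
              "M": "m", "F": "f", "B": "b"}
_TYPE_CODES = {"O": "occurrence", "R": "registration",
               "occurrence": "occurrence", "registration": "registration"}


def read_raw_deaths(
    path: str | Path,
    fields: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a raw weekly death-count CSV into a normalized DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row containing the nine documented fields.
    fields
        Optional mapping from canonical field names (:data:`RAW_FIELDS`)
        to the header spellings used in this file.

    Returns
    -------
    pandas.DataFrame
        Columns ``pop_name, area, year, week, sex, age_start, age_interval,
        data_type, access, deaths``.  ``age_start`` is NaN for unknown-age
        rows; ``age_interval`` is ``inf`` for the open-ended group and NaN
        for unknown-age rows; ``sex`` is one of ``m``/``f``/``b``.

    Raises
    ------
    FormatError
        If a required column is missing (the message names it).
    ValidationError
        If a row has negative deaths, week < 1, or age intervals overlap
        within a (pop, area, year, week, sex) stratum; the message cites
        the offending row numbers (1-based data rows).
    """
    rename = {v: k for k, v in (fields or {}).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=rename)
    for col in RAW_FIELDS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    out = pd.DataFrame(
        {
            "pop_name": df["PopName"].astype(str),
            "area": df["Area"].astype(str),
            "year": pd.to_numeric(df["Year"]).astype(int),
            "week": pd.to_numeric(df["Week"]).astype(int),
            "sex": df["Sex"].map(_SEX_CODES),
            "data_type": df["Type"].map(_TYPE_CODES),
            "access": df["Access"].astype(str),
            "deaths": pd.to_numeric(df["Deaths"]).astype(float),
        }
    )
    if out["sex"].isna().any():
        bad = df.loc[out["sex"].isna(), "Sex"].unique()
        raise ValidationError(f"unrecognized sex codes {sorted(bad)}")

    unk = df["Age"].str.upper() == UNKNOWN_AGE_TOKEN
    out["age_start"] = np.where(unk, np.nan, pd.to_numeric(df["Age"].where(~unk, "0")))
    open_iv = df["AgeInterval"] == OPEN_INTERVAL_TOKEN
    iv = pd.to_numeric(df["AgeInterval"].where(~open_iv, "0"), errors="coerce")
    out["age_interval"] = np.where(unk, np.nan, np.where(open_iv, math.inf, iv))

    neg = out.index[out["deaths"] < 0] + 1
    if len(neg):
        raise ValidationError(f"negative death counts at data row(s) {list(neg)}")
    badweek = out.index[out["week"] < 1] + 1
    if len(badweek):
        raise ValidationError(f"week < 1 at data row(s) {list(badweek)}")

    _check_no_overlap(out)
    return out[["pop_name", "area", "year", "week", "sex",
                "age_start", "age_interval", "data_type", "access", "deaths"]]


def _check_no_overlap(df: pd.DataFrame) -> None:
    known = df[df["age_start"].notna()]
    for key, grp in known.groupby(["pop_name", "area", "year", "week", "sex"]):
        ivs = sorted(
            zip(grp["age_start"], grp["age_start"] + grp["age_interval"])
        )
        for (a0, a1), (b0, _b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValidationError(
                    f"overlapping age intervals in stratum {key}: "
                    f"[{a0}, {a1}) and [{b0}, ...)"
                )


def write_raw_deaths(df: pd.DataFrame, path: str | Path) -> None:
    """Write a normalized raw table back to the raw CSV dialect."""
    rev_sex = {"m": "m", "f": "f", "b": "b"}
    rev_type = {"occurrence": "O", "registration": "R"}
    age = df["age_start"].map(
        lambda a: UNKNOWN_AGE_TOKEN if pd.isna(a) else f"{a:g}"
    )
    iv = [
        "" if pd.isna(a) else (OPEN_INTERVAL_TOKEN if math.isinf(v) else f"{v:g}")
        for a, v in zip(df["age_start"], df["age_interval"])
    ]
    out = pd.DataFrame(
        {
            "PopName": df["pop_name"],
            "Area": df["area"],
            "Year": df["year"],
            "Week": df["week"],
            "Sex": df["sex"].map(rev_sex),
            "Age": age,
            "AgeInterval": iv,
            "Type": df["data_type"].map(rev_type),
            "Access": df["access"],
            "Deaths": df["deaths"].map(lambda d: f"{d:.17g}"),
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Harmonized output table

def _group_suffix(group: tuple[float, float]) -> str:
    lo, hi = group
    return f"{int(lo)}p" if math.isinf(hi) else f"{int(lo)}_{int(hi) - 1}"


def stmf_columns(
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> list[str]:
    """Column order of the harmonized output CSV for a given age grouping."""
    d = [f"D{_group_suffix(g)}" for g in groups] + ["DTotal"]
    r = [f"R{_group_suffix(g)}" for g in groups] + ["RTotal"]
    return ["CountryCode", "Year", "Week", "Sex"] + d + r + ["Split", "SplitSex", "Forecast"]


def write_stmf_output(
    records: pd.DataFrame,
    path: str | Path,
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
    tolerance: float = 1e-6,
    tidy: bool = False,
) -> None:
    """Write harmonized records to CSV in the standard column order.

    Parameters
    ----------
    records
        Wide table with the columns of :func:`stmf_columns` for *groups*.
    tolerance
        Maximum allowed relative discrepancy between the sum of the group
        counts and the all-ages total; a worse record refuses to write.
    tidy
        If true, write a long/tidy variant instead (one row per age group,
        columns ``CountryCode, Year, Week, Sex, AgeGroup, Deaths, Rate,
        Split, SplitSex, Forecast``).

    Raises
    ------
    ValidationError
        If a record violates the group-sum invariant or a flag is not 0/1;
        the message reports the offending (country, year, week, sex) key.
    """
    cols = stmf_columns(groups)
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise FormatError(f"records lack required columns {missing}")
    dcols = [f"D{_group_suffix(g)}" for g in groups]

    sums = records[dcols].sum(axis=1)
    denom = records["DTotal"].where(records["DTotal"] != 0, 1.0)
    bad = (sums - records["DTotal"]).abs() / denom.abs() > tolerance
    if bad.any():
        key = records.loc[bad.idxmax(), ["CountryCode", "Year", "Week", "Sex"]]
        raise ValidationError(
            f"group counts do not sum to DTotal for {tuple(key)} "
            f"(sum {sums[bad.idxmax()]!r} vs total {records.loc[bad.idxmax(), 'DTotal']!r})"
        )
    for flag in ("Split", "SplitSex", "Forecast"):
        if not records[flag].isin([0, 1]).all():
            key = records.loc[~records[flag].isin([0, 1]),
                              ["CountryCode", "Year", "Week", "Sex"]].iloc[0]
            raise ValidationError(f"non-binary {flag} flag for {tuple(key)}")

    if tidy:
        long_rows = records.melt(
            id_vars=["CountryCode", "Year", "Week", "Sex", "Split", "SplitSex", "Forecast"],
            value_vars=dcols,
            var_name="AgeGroup",
            value_name="Deaths",
        )
        suffix_to_label = {f"D{_group_suffix(g)}": age_group_label(g) for g in groups}
        long_rows["AgeGroup"] = long_rows["AgeGroup"].map(suffix_to_label)
        rates = records.melt(
            id_vars=["CountryCode", "Year", "Week", "Sex"],
            value_vars=[f"R{_group_suffix(g)}" for g in groups],
            value_name="Rate",
        )["Rate"]
        long_rows["Rate"] = rates.to_numpy()
        long_rows = long_rows[["CountryCode", "Year", "Week", "Sex", "AgeGroup",
                               "Deaths", "Rate", "Split", "SplitSex", "Forecast"]]
        long_rows.to_csv(path, index=False, float_format="%.17g")
        return

    records[cols].to_csv(path, index=False, float_format="%.17g")


def read_stmf_output(
    path: str | Path,
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> pd.DataFrame:
    """Read a harmonized output CSV written by :func:`write_stmf_output`."""
    df = pd.read_csv(path)
    cols = stmf_columns(groups)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")
    return df[cols]
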