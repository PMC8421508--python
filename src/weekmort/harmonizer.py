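"""Harmonize weekly death counts into standard age groups by sex.

Sources publish weekly all-cause death counts on heterogeneous age scales —
five-year groups, very broad bands such as 0-17 / 18-64 / 65+, sometimes
with a residual "unknown age" count, sometimes for both sexes combined.
This module redistributes unknown-age deaths and disaggregates broad age
and combined-sex counts onto the five standard groups (0-14, 15-64, 65-74,
75-84, 85+) using annual age- and sex-specific death distributions.

All three adjustments are proportional allocations, so they conserve the
total death count of each (year, week, sex) stratum exactly (up to floating
point).  No smoothing and no undercount adjustment is applied anywhere.

The splitting rules, per stratum (year y, week w):

* broad-to-standard age split, for a target group [x, x+a) nested in a
  source interval [x, x+b):

      D̂_y^w(x, x+a) = D_y^w(x, x+b) * D_y(x, x+a) / D_y(x, x+b)

  where D_y are annual death counts (observed or forecast);

* combined-sex split, per age group, using the annual sex ratio:

      D̂_y^{w,males} = D_y^{w,total} * D_y^{males} / D_y^{total}

* unknown-age redistribution: proportional to the stratum's own known-age
  counts, falling back to the annual age distribution of the same year and
  sex when the week has no known-age deaths.

Age groups are ``(start, end)`` tuples with ``math.inf`` for the open end.
Weekly and annual group counts are passed as pandas Series indexed by those
tuples.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_AGE_GROUPS",
    "age_group_label",
    "parse_age_group_label",
    "redistribute_unknown_age",
    "split_age_groups",
    "split_sex",
    "annual_group_series",
    "harmonize_table",
    "HarmonizationError",
]

#: Default output age grouping: child, adult, and three old-age bands.
STANDARD_AGE_GROUPS: tuple[tuple[float, float], ...] = (
    (0, 15),
    (15, 65),
    (65, 75),
    (75, 85),
    (85, math.inf),
)


class HarmonizationError(ValueError):
    """Raised when a split is impossible (misaligned groups, zero denominator)."""


def age_group_label(group: tuple[float, float]) -> str:
    """Human-readable label, e.g. ``(0, 15) -> '0-14'``, ``(85, inf) -> '85+'``."""
    lo, hi = group
    if math.isinf(hi):
        return f"{int(lo)}+"
    return f"{int(lo)}-{int(hi) - 1}"


def parse_age_group_label(label: str) -> tuple[float, float]:
    """Inverse of :func:`age_group_label`."""
    if label.endswith("+"):
        return (float(label[:-1]), math.inf)
    lo, hi = label.split("-")
    return (float(lo), float(hi) + 1)


def redistribute_unknown_age(
    known: pd.Series,
    unknown: float,
    annual_distribution: pd.Series | None = None,
) -> pd.Series:
    """Allocate unknown-age deaths proportionally over known-age counts.

    Parameters
    ----------
    known
        Known-age weekly counts indexed by age-group tuple.
    unknown
        Deaths with unknown age in the same stratum (>= 0).
    annual_distribution
        Annual death counts by the same groups for the stratum's year and
        sex; used as the allocation weights when the week itself has no
        known-age deaths.

    Returns
    -------
    pandas.Series
        Counts on the same index; total equals ``known.sum() + unknown``.

    Raises
    ------
    HarmonizationError
        If ``unknown > 0`` but both the weekly counts and the annual
        fallback distribution are all zero (or absent).
    """
    if unknown < 0:
        raise HarmonizationError(f"unknown-age deaths must be >= 0, got {unknown}")
    if unknown == 0:
        return known.astype(float)

    weights = known.astype(float)
    if weights.sum() == 0:
        if annual_distribution is None or float(annual_distribution.sum()) == 0:
            raise HarmonizationError(
                "cannot redistribute unknown-age deaths: weekly known-age "
                "counts and annual fallback distribution are both empty"
            )
        weights = annual_distribution.reindex(known.index).fillna(0.0).astype(float)
    return known.astype(float) + unknown * weights / weights.sum()


def _nesting_source(
    target: tuple[float, float], sources: Iterable[tuple[float, float]]
) -> tuple[float, float] | None:
    for src in sources:
        if src[0] <= target[0] and target[1] <= src[1]:
            return src
    return None


def split_age_groups(
    weekly: pd.Series,
    annual: pd.Series,
    targets: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> tuple[pd.Series, int]:
    """Split weekly counts on broad source intervals into *targets*.

    Every target group must nest inside exactly one source interval; the
    allocated counts within each source interval sum exactly to the source
    count (conservation).

    Parameters
    ----------
    weekly
        Weekly counts indexed by source age-group tuples (non-overlapping).
    annual
        Annual death counts indexed by the target groups, observed or
        forecast, for the same year and sex.
    targets
        Output age grouping (default the five standard groups).

    Returns
    -------
    (counts, split_flag)
        Counts on the target index, and 1 if any source interval strictly
        contained more than one target group, else 0 (pass-through).

    Raises
    ------
    HarmonizationError
        If a target straddles two source intervals, a target is not covered
        by any source, or a source with positive deaths has a zero annual
        denominator.
    """
    sources = list(weekly.index)
    out = pd.Series(0.0, index=pd.Index(targets, tupleize_cols=False))
    children: dict[tuple[float, float], list[tuple[float, float]]] = {s: [] for s in sources}
    for tgt in targets:
        src = _nesting_source(tgt, sources)
        if src is None:
            overlapping = [
                s for s in sources if s[0] < tgt[1] and tgt[0] < s[1]
            ]
            raise HarmonizationError(
                f"target group {age_group_label(tgt)} does not nest in a single "
                f"source interval (overlaps {[age_group_label(s) for s in overlapping]})"
            )
        children[src].append(tgt)

    split_flag = 0
    for src, tgts in children.items():
        w = float(weekly.loc[[src]].iloc[0])
        if len(tgts) == 1 and tgts[0] == src:
            out.loc[[tgts[0]]] = w
            continue
        split_flag = 1
        denom = float(annual.reindex(pd.Index(tgts, tupleize_cols=False)).fillna(0.0).sum())
        if denom == 0:
            if w == 0:
                continue
            raise HarmonizationError(
                f"annual death count is zero over source interval "
                f"{age_group_label(src)} but weekly count is {w}"
            )
        for tgt in tgts:
            out.loc[[tgt]] = w * float(annual.loc[[tgt]].iloc[0]) / denom
    return out, split_flag


def split_sex(
    weekly_total: pd.Series,
    annual_male: pd.Series,
    annual_total: pd.Series,
) -> tuple[pd.Series, pd.Series, int]:
    """Split both-sex weekly counts into male and female counts per group.

    The male share of each age group is the annual male share of deaths in
    that group; female = total - male, so the sexes sum to the input
    exactly.

    Returns ``(male, female, split_sex_flag)`` with flag 1 (the input
    lacked sex detail by construction of this call).

    Raises
    ------
    HarmonizationError
        If a group has weekly deaths but zero annual both-sex deaths.
    """
    male = pd.Series(0.0, index=weekly_total.index)
    for grp in weekly_total.index:
        w = float(weekly_total.loc[[grp]].iloc[0])
        if w == 0:
            continue
        tot = float(annual_total.reindex(weekly_total.index).loc[[grp]].iloc[0])
        if not tot > 0:
            raise HarmonizationError(
                f"annual both-sex deaths are zero in group {age_group_label(grp)} "
                f"but weekly total is {w}"
            )
        male.loc[[grp]] = w * float(annual_male.loc[[grp]].iloc[0]) / tot
    female = weekly_total.astype(float) - male
    return male, female, 1


# ---------------------------------------------------------------------------
# Table-level harmonization

def annual_group_series(
    annual: pd.DataFrame,
    year: int,
    sex: str,
    column: str = "deaths",
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> pd.Series:
    """Extract one year/sex slice of an annual table as a group-indexed Series.

    *annual* is a long table with columns ``year, sex, age_start, age_end,
    deaths, exposure`` (and optionally ``source``).  Annual entries are
    aggregated onto *groups* (each annual row must nest in one group).
    """
    sl = annual[(annual["year"] == year) & (annual["sex"] == sex)]
    out = pd.Series(0.0, index=pd.Index(groups, tupleize_cols=False))
    for _, row in sl.iterrows():
        grp = _nesting_source((row["age_start"], row["age_end"]), groups)
        if grp is None:
            raise HarmonizationError(
                f"annual interval [{row['age_start']}, {row['age_end']}) does not "
                f"nest in the target grouping"
            )
        out.loc[[grp]] += float(row[column])
    return out


def harmonize_table(
    raw: pd.DataFrame,
    annual: pd.DataFrame,
    targets: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> pd.DataFrame:
    """Harmonize a raw weekly table into target age groups by sex.

    Order of operations per (year, week, input-sex) stratum: unknown-age
    redistribution, then age splitting, then sex splitting of both-sex-only
    strata.  Strata that already carry sex detail pass through sex splitting
    untouched (flag 0).

    Parameters
    ----------
    raw
        Normalized raw table from :func:`weekmort.raw_io.read_raw_deaths`:
        columns ``year, week, sex, age_start, age_interval, deaths`` (sex in
        {"m", "f", "b"}; unknown age encoded as NaN ``age_start``).
    annual
        Long annual table (see :func:`annual_group_series`) with a
        ``source`` column ("observed" or "forecast") used to set the
        Forecast flag.

    Returns
    -------
    pandas.DataFrame
        Long table with columns ``year, week, sex, age_start, age_end,
        deaths, split, split_sex, forecast`` covering sexes "m", "f", "b"
        and the target groups.
    """
    records: list[dict] = []
    target_index = pd.Index(list(targets), tupleize_cols=False)

    forecast_years = set(
        annual.loc[annual.get("source", pd.Series(dtype=object)) == "forecast", "year"].unique()
    ) if "source" in annual.columns else set()

    for (year, week), stratum in raw.groupby(["year", "week"], sort=True):
        year = int(year)
        week = int(week)
        sexes_present = set(stratum["sex"].unique())
        by_sex: dict[str, pd.Series] = {}
        flags: dict[str, tuple[int, int]] = {}

        input_sexes = ["m", "f"] if {"m", "f"} <= sexes_present else ["b"]
        for sex in input_sexes:
            part = stratum[stratum["sex"] == sex]
            if part.empty:
                raise HarmonizationError(
                    f"stratum (year={year}, week={week}) lacks sex {sex!r}"
                )
            unknown = float(part.loc[part["age_start"].isna(), "deaths"].sum())
            known = part[part["age_start"].notna()]
            src_groups = [
                (float(a), float(a) + float(b))
                for a, b in zip(known["age_start"], known["age_interval"])
            ]
            weekly = pd.Series(
                known["deaths"].astype(float).to_numpy(),
                index=pd.Index(src_groups, tupleize_cols=False),
            )
            weekly = weekly.groupby(level=0).sum()  # duplicate intervals summed
            weekly.index = pd.Index(list(weekly.index), tupleize_cols=False)

            annual_deaths_src = annual_group_series(
                annual, year, sex, "deaths", list(weekly.index)
            ) if unknown > 0 and weekly.sum() == 0 else None
            weekly = redistribute_unknown_age(weekly, unknown, annual_deaths_src)

            annual_deaths_tgt = annual_group_series(annual, year, sex, "deaths", targets)
            counts, split_flag = split_age_groups(weekly, annual_deaths_tgt, targets)
            by_sex[sex] = counts
            flags[sex] = (split_flag, 0)

        if input_sexes == ["b"]:
            annual_m = annual_group_series(annual, year, "m", "deaths", targets)
            annual_b = annual_group_series(annual, year, "b", "deaths", targets)
            male, female, _ = split_sex(by_sex["b"], annual_m, annual_b)
            split_flag = flags["b"][0]
            by_sex["m"], by_sex["f"] = male, female
            flags["m"] = flags["f"] = flags["b"] = (split_flag, 1)
        else:
            by_sex["b"] = by_sex["m"].add(by_sex["f"], fill_value=0.0)
            any_split = max(flags["m"][0], flags["f"][0])
            flags["b"] = (any_split, 0)

        forecast = int(year in forecast_years)
        for sex in ("m", "f", "b"):
            counts = by_sex[sex].reindex(target_index).fillna(0.0)
            for grp in target_index:
                records.append(
                    {
                        "year": year,
                        "week": week,
                        "sex": sex,
                        "age_start": grp[0],
                        "age_end": grp[1],
                        "deaths": float(counts.loc[[grp]].iloc[0]),
                        "split": flags[sex][0],
                        "split_sex": flags[sex][1],
                        "forecast": forecast,
                    }
                )
    out = pd.DataFrame.from_records(records)
    # Split/SplitSex describe the shape of the source data, which is an
    # annual property of each series: flag the whole year if any week of it
    # needed the adjustment.
    for col in ("split", "split_sex"):
        out[col] = out.groupby("year")[col].transform("max")
    return out
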