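"""Week numbering schemes and the 52-week statistical year.

Weekly death counts are labelled by (year, week).  The default convention is
ISO-8601: weeks start on Monday and week 1 is the week containing the year's
first Thursday (equivalently, January 4), so every week has exactly 7 days
and a year has 52 or 53 labelled weeks.  A few national statistical offices
deviate: US data use Sunday-start weeks, England & Wales and Northern
Ireland use Saturday-start weeks, and Australian data number 7-day blocks
from January 1.

For the Sunday- and Saturday-start schemes we anchor week 1 as the week, in
the scheme's own alignment, that contains January 4 — the same anchor date
ISO-8601 uses.  This keeps all 7-day schemes mutually consistent and reduces
to ISO-8601 exactly when the start day is Monday.

The harmonized statistical year always has 52 weeks: a source week 53 is
merged into week 52 of the same year (or optionally dropped), conserving
total deaths.
"""

from __future__ import annotations

import datetime as _dt
import logging
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeekScheme",
    "DEFAULT_COUNTRY_SCHEMES",
    "scheme_for_country",
    "date_to_week",
    "clamp_to_52",
]


class WeekScheme(str, Enum):
    """Supported week-numbering conventions."""

    ISO_MONDAY = "iso_monday"
    SUNDAY_START = "sunday_start"
    SATURDAY_START = "saturday_start"
    JAN1_START = "jan1_start"


#: Python weekday() index of the first day of the week for each 7-day scheme.
_START_WEEKDAY = {
    WeekScheme.ISO_MONDAY: 0,  # Monday
    WeekScheme.SUNDAY_START: 6,
    WeekScheme.SATURDAY_START: 5,
}

#: Country codes that do not follow ISO-8601 Monday-start weeks.
DEFAULT_COUNTRY_SCHEMES: Mapping[str, WeekScheme] = {
    "USA": WeekScheme.SUNDAY_START,
    "GBRTENW": WeekScheme.SATURDAY_START,
    "GBR_NIR": WeekScheme.SATURDAY_START,
    "AUS": WeekScheme.JAN1_START,
}


def scheme_for_country(
    country: str,
    overrides: Mapping[str, WeekScheme | str] | None = None,
) -> WeekScheme:
    """Return the week scheme for a country code, default ISO Monday-start."""
    table: dict[str, WeekScheme] = dict(DEFAULT_COUNTRY_SCHEMES)
    if overrides:
        table.update({k: WeekScheme(v) for k, v in overrides.items()})
    return table.get(country, WeekScheme.ISO_MONDAY)


def _week_start(date: _dt.date, start_weekday: int) -> _dt.date:
    """The first day (on or before *date*) of the week containing *date*."""
    return date - _dt.timedelta(days=(date.weekday() - start_weekday) % 7)


def date_to_week(
    date: _dt.date | _dt.datetime | str,
    scheme: WeekScheme | str = WeekScheme.ISO_MONDAY,
) -> tuple[int, int]:
    """Map a calendar date to its (year, week) label under *scheme*.

    Parameters
    ----------
    date
        A ``datetime.date``, ``datetime.datetime`` or ISO date string.
    scheme
        Week-numbering convention; see :class:`WeekScheme`.

    Returns
    -------
    tuple of int
        ``(year, week)``.  For the 7-day schemes the year is the week-year
        (a date near January 1 may belong to the previous year's last week);
        for ``jan1_start`` it is always the calendar year and days 365-366
        fall into a short week 53 that :func:`clamp_to_52` later absorbs.

    Examples
    --------
    >>> date_to_week("2020-01-01")
    (2020, 1)
    >>> date_to_week("2016-01-01")
    (2015, 53)
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, _dt.datetime):
        date = date.date()
    scheme = WeekScheme(scheme)

    if scheme is WeekScheme.ISO_MONDAY:
        iso = date.isocalendar()
        return iso[0], iso[1]

    if scheme is WeekScheme.JAN1_START:
        doy = date.timetuple().tm_yday
        return date.year, (doy - 1) // 7 + 1

    start = _START_WEEKDAY[scheme]
    ws = _week_start(date, start)
    # The week belongs to year Y iff its start lies in [week1_start(Y),
    # week1_start(Y+1)); week 1 of Y is the aligned week containing Jan 4.
    for year in (date.year + 1, date.year, date.year - 1):
        w1 = _week_start(_dt.date(year, 1, 4), start)
        if ws >= w1:
            return year, (ws - w1).days // 7 + 1
    raise AssertionError("unreachable: week-year search failed")


def clamp_to_52(
    data: pd.DataFrame | pd.Series,
    value_columns: Iterable[str] | None = None,
    mode: str = "merge",
) -> pd.DataFrame | pd.Series:
    """Enforce the 52-week statistical year.

    Week-53 records are merged into week 52 of the same year by summing the
    count columns (``mode="merge"``, the default, conserves total deaths) or
    removed (``mode="drop"``).  Every merge or drop is logged.

    Parameters
    ----------
    data
        Either a Series with a (year, week) MultiIndex, or a DataFrame with
        ``year`` and ``week`` columns.
    value_columns
        For a DataFrame, the numeric columns to sum when merging; defaults
        to all columns other than the keys.  Non-summed columns take the
        week-52 row's values.
    mode
        ``"merge"`` or ``"drop"``.

    Raises
    ------
    ValueError
        If any week label is outside 1..53 or *mode* is unknown.
    """
    if mode not in ("merge", "drop"):
        raise ValueError(f"unknown week-53 mode {mode!r}")

    if isinstance(data, pd.Series):
        frame = data.rename("value").reset_index()
        frame.columns = ["year", "week", "value"]
        out = clamp_to_52(frame, value_columns=["value"], mode=mode)
        return out.set_index(["year", "week"])["value"]

    df = data.copy()
    if (df["week"] < 1).any() or (df["week"] > 53).any():
        bad = df.loc[(df["week"] < 1) | (df["week"] > 53), "week"].unique()
        raise ValueError(f"week labels outside 1..53: {sorted(bad)}")

    mask53 = df["week"] == 53
    if not mask53.any():
        return df

    if value_columns is None:
        value_columns = [
            c for c in df.columns
            if c not in ("year", "week") and pd.api.types.is_numeric_dtype(df[c])
        ]
    value_columns = list(value_columns)
    key_cols = [c for c in df.columns if c not in value_columns and c != "week"]

    for _, grp in df[mask53].groupby(key_cols, dropna=False):
        logger.info(
            "week 53 %s for stratum %s (%d row(s))",
            "merged into week 52" if mode == "merge" else "dropped",
            dict(zip(key_cols, grp.iloc[0][key_cols])),
            len(grp),
        )

    if mode == "drop":
        return df[~mask53].reset_index(drop=True)

    extra = df[mask53].copy()
    extra["week"] = 52
    merged = (
        pd.concat([df[~mask53], extra], ignore_index=True)
        .groupby(key_cols + ["week"], as_index=False, dropna=False, sort=False)[value_columns]
        .sum()
    )
    return merged[df.columns.tolist()].sort_values(key_cols + ["week"]).reset_index(drop=True)
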