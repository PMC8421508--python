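"""Person-week death rates, reference baselines and weekly excess mortality.

Weekly death rates are scaled so they are directly comparable with annual
rates: with annual exposure E_y person-years,

    m_y^w = D_y^w / (E_y / 52),

i.e. deaths per person-week of exposure.  A year of uniform weekly deaths
then has mean weekly rate equal to the annual rate.

Excess mortality is observed minus expected, where the expected weekly
schedule comes from a configurable baseline over reference years — by
default the week-specific mean over a five-year reference window (e.g. the
2015-19 average for target 2020).  Negative excess (a deficit) is
meaningful and preserved.  Because recent weeks are incomplete due to the
registration lag, a completeness cutoff week can exclude them from the
excess output; no completeness adjustment is ever applied to the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "weekly_rate",
    "baseline",
    "excess",
    "ExcessResult",
    "BASELINE_METHODS",
]


def weekly_rate(deaths, annual_exposure):
    """Death rate per person-week: ``deaths / (annual_exposure / 52)``.

    Both arguments may be scalars or aligned array-likes.  Raises
    ``ValueError`` on non-positive exposure.
    """
    exposure = np.asarray(annual_exposure, dtype=float)
    if (exposure <= 0).any():
        raise ValueError("annual exposure must be > 0")
    out = np.asarray(deaths, dtype=float) / (exposure / 52.0)
    return float(out) if out.ndim == 0 else out


# --- baseline registry ------------------------------------------------------
# Each method maps a (reference-years x weeks) rate table and the target year
# to an expected rate per week.  The registry is extensible: users may
# register additional reference-level definitions.

def _week_mean(table: pd.DataFrame, target_year: int) -> pd.Series:
    return table.mean(axis=0)


def _week_median(table: pd.DataFrame, target_year: int) -> pd.Series:
    return table.median(axis=0)


def _week_mean_trend(table: pd.DataFrame, target_year: int) -> pd.Series:
    """Per-week OLS of rate on year, evaluated at the target year."""
    if len(table.index) < 3:
        raise ValueError("week_mean_trend needs >= 3 reference years")
    years = table.index.to_numpy(dtype=float)
    out = {}
    for week in table.columns:
        slope, intercept, *_ = stats.linregress(years, table[week].to_numpy(dtype=float))
        out[week] = intercept + slope * target_year
    return pd.Series(out)


def _annual_min_year(table: pd.DataFrame, target_year: int) -> pd.Series:
    """Weekly rates of the reference year with the lowest annual mean rate."""
    best = table.mean(axis=1).idxmin()
    return table.loc[best].copy()


def _specific_year(table: pd.DataFrame, target_year: int) -> pd.Series:
    if len(table.index) != 1:
        raise ValueError(
            "specific_year expects exactly one reference year; "
            f"got {list(table.index)}"
        )
    return table.iloc[0].copy()


def _week_mean_excluding_shocks(table: pd.DataFrame, target_year: int) -> pd.Series:
    """Week-specific trimmed mean (drops the extreme year at each end)."""
    if len(table.index) < 3:
        return table.mean(axis=0)
    frac = 1.0 / len(table.index)  # trim one year per tail
    return pd.Series(
        stats.trim_mean(table.to_numpy(dtype=float), frac, axis=0),
        index=table.columns,
    )


BASELINE_METHODS: dict[str, Callable[[pd.DataFrame, int], pd.Series]] = {
    "week_mean": _week_mean,
    "week_median": _week_median,
    "week_mean_trend": _week_mean_trend,
    "annual_min_year": _annual_min_year,
    "specific_year": _specific_year,
    "week_mean_excluding_shocks": _week_mean_excluding_shocks,
}


def baseline(
    history: pd.DataFrame | pd.Series,
    method: str = "week_mean",
    reference_years: Sequence[int] | None = None,
    target_year: int | None = None,
) -> pd.Series:
    """Expected weekly rate schedule from reference-year history.

    Parameters
    ----------
    history
        Either a DataFrame with years as rows and weeks 1..52 as columns,
        or a Series with a (year, week) MultiIndex.
    method
        One of :data:`BASELINE_METHODS` (default ``week_mean``, the
        week-specific average over the reference years).
    reference_years
        Years to use; default all years in *history*.
    target_year
        Needed by trend-type methods; defaults to last reference year + 1.

    Returns
    -------
    pandas.Series
        Expected rate per week, indexed by week.
    """
    if isinstance(history, pd.Series):
        history = history.unstack(level=-1)
    if reference_years is not None:
        missing = [y for y in reference_years if y not in history.index]
        if missing:
            raise ValueError(f"reference years missing from history: {missing}")
        history = history.loc[list(reference_years)]
    if history.empty:
        raise ValueError("empty reference window")
    if method not in BASELINE_METHODS:
        raise ValueError(
            f"unknown baseline method {method!r}; known: {sorted(BASELINE_METHODS)}"
        )
    if target_year is None:
        target_year = int(history.index.max()) + 1
    expected = BASELINE_METHODS[method](history, target_year)
    expected.index.name = "week"
    return expected


@dataclass
class ExcessResult:
    """Weekly excess mortality for one series.

    ``table`` has one row per week with columns ``observed_rate,
    expected_rate, excess_rate, observed_deaths, expected_deaths,
    excess_deaths``; count columns are present when an exposure was given
    (count = rate * exposure / 52).
    """

    table: pd.DataFrame
    method: str
    reference_years: list[int]

    @property
    def cumulative_excess_deaths(self) -> float:
        return float(self.table["excess_deaths"].sum())

    @property
    def cumulative_excess_rate(self) -> float:
        return float(self.table["excess_rate"].sum())


def excess(
    observed: pd.Series,
    expected: pd.Series,
    annual_exposure: float | None = None,
    method: str = "week_mean",
    reference_years: Sequence[int] = (),
) -> ExcessResult:
    """Per-week excess = observed - expected, for rates and counts.

    Parameters
    ----------
    observed, expected
        Weekly rate series indexed by week; the indices must align (an
        error lists missing weeks).
    annual_exposure
        Person-years of the target year; enables the count columns via
        count = rate * exposure / 52.

    Raises
    ------
    ValueError
        If week indices are misaligned.
    """
    obs_weeks = set(observed.index)
    exp_weeks = set(expected.index)
    if obs_weeks != exp_weeks:
        raise ValueError(
            "misaligned week indices: missing from expected "
            f"{sorted(obs_weeks - exp_weeks)}, missing from observed "
            f"{sorted(exp_weeks - obs_weeks)}"
        )
    expected = expected.reindex(observed.index)
    table = pd.DataFrame(
        {
            "observed_rate": observed.astype(float),
            "expected_rate": expected.astype(float),
        }
    )
    table["excess_rate"] = table["observed_rate"] - table["expected_rate"]
    if annual_exposure is not None:
        pw = annual_exposure / 52.0
        table["observed_deaths"] = table["observed_rate"] * pw
        table["expected_deaths"] = table["expected_rate"] * pw
        table["excess_deaths"] = table["excess_rate"] * pw
    return ExcessResult(
        table=table, method=method, reference_years=[int(y) for y in reference_years]
    )
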