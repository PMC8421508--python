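"""Consistency checks and outlier diagnostics for harmonized weekly data.

Every dataset update is validated with a machine-readable report rather
than exceptions: issues are documented, never silently fixed, and
validation never mutates the data.  Three families of checks:

* internal — age-group counts sum to the all-ages total; male + female
  equal the both-sex series; processed weekly totals match the raw input
  totals; sex ratios of death rates stay within a plausibility band;
* external — weekly counts summed over a year are close to official annual
  figures (default tolerance 1%);
* outliers — robust per-week z-scores (median/MAD across reference years)
  flag implausible weeks for inspection.  Pandemic weeks are exactly the
  signal of interest, which is why the scale estimate is robust: a genuine
  shock must not inflate the dispersion that is supposed to detect it.

All numeric thresholds are configurable; the defaults are documented
choices, not data-derived constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CheckResult",
    "ValidationReport",
    "check_internal",
    "check_external",
    "detect_outliers",
]


@dataclass
class CheckResult:
    """Outcome of one check at one scope."""

    check_id: str
    scope: str
    status: str  # pass | warn | fail | skipped
    metric: float | None
    threshold: float | None
    detail: str = ""


@dataclass
class ValidationReport:
    """Collection of check results with JSON-lines serialization."""

    results: list[CheckResult]

    @property
    def n_fail(self) -> int:
        return sum(r.status == "fail" for r in self.results)

    @property
    def n_warn(self) -> int:
        return sum(r.status == "warn" for r in self.results)

    def failures(self) -> list[CheckResult]:
        return [r for r in self.results if r.status == "fail"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(asdict(r)) for r in self.results)

    def summary(self) -> str:
        n = len(self.results)
        return (
            f"{n} check(s): {n - self.n_fail - self.n_warn} pass, "
            f"{self.n_warn} warn, {self.n_fail} fail"
        )


def check_internal(
    harmonized: pd.DataFrame,
    raw_totals: pd.Series | None = None,
    rates: pd.DataFrame | None = None,
    tolerance: float = 1e-6,
    sex_ratio_band: tuple[float, float] = (0.5, 5.0),
) -> ValidationReport:
    """Internal consistency checks on a harmonized long table.

    Parameters
    ----------
    harmonized
        Long table from :func:`weekmort.harmonizer.harmonize_table`
        (columns ``year, week, sex, age_start, age_end, deaths``), where
        sex "b" rows hold the all-ages-by-group both-sex series.
    raw_totals
        Optional raw per-(year, week) total deaths (both sexes, all ages)
        to compare processed totals against.
    rates
        Optional long table with a ``rate`` column in the same layout,
        used for the sex-ratio band check.
    tolerance
        Relative tolerance for the sum checks.
    sex_ratio_band
        Plausibility band for male/female rate ratios per age group.

    Returns
    -------
    ValidationReport
        One ``sex_sum`` entry per (year, week, group), one ``raw_total``
        entry per (year, week) when raw totals are given, and one
        ``sex_ratio`` entry per (year, week, group) when rates are given.
    """
    results: list[CheckResult] = []

    def reldiff(a: float, b: float) -> float:
        return abs(a - b) / (abs(b) if b != 0 else 1.0)

    key = ["year", "week", "age_start", "age_end"]
    wide = harmonized.pivot_table(
        index=key, columns="sex", values="deaths", aggfunc="sum"
    )
    for idx, row in wide.iterrows():
        year, week, a0, a1 = idx
        scope = f"year={int(year)}/week={int(week)}/age={a0:g}-{a1:g}"
        d = reldiff(row.get("m", 0.0) + row.get("f", 0.0), row.get("b", 0.0))
        results.append(
            CheckResult(
                "sex_sum", scope,
                "pass" if d <= tolerance else "fail",
                float(d), tolerance,
                "male + female vs both-sex count",
            )
        )

    if raw_totals is not None:
        processed = (
            harmonized[harmonized["sex"] == "b"]
            .groupby(["year", "week"])["deaths"].sum()
        )
        for (year, week), value in processed.items():
            scope = f"year={int(year)}/week={int(week)}"
            if (year, week) not in raw_totals.index:
                results.append(
                    CheckResult("raw_total", scope, "skipped", None, tolerance,
                                "no raw total available")
                )
                continue
            d = reldiff(float(value), float(raw_totals.loc[(year, week)]))
            results.append(
                CheckResult(
                    "raw_total", scope,
                    "pass" if d <= tolerance else "fail",
                    float(d), tolerance,
                    "processed weekly total vs raw input total",
                )
            )

    if rates is not None:
        rwide = rates.pivot_table(
            index=key, columns="sex", values="rate", aggfunc="sum"
        )
        lo, hi = sex_ratio_band
        for idx, row in rwide.iterrows():
            year, week, a0, a1 = idx
            f = float(row.get("f", np.nan))
            m = float(row.get("m", np.nan))
            if not (f > 0) or not np.isfinite(m):
                continue
            ratio = m / f
            scope = f"year={int(year)}/week={int(week)}/age={a0:g}-{a1:g}"
            results.append(
                CheckResult(
                    "sex_ratio", scope,
                    "pass" if lo <= ratio <= hi else "warn",
                    float(ratio), None,
                    f"male/female rate ratio, band [{lo}, {hi}]",
                )
            )
    return ValidationReport(results)


def check_external(
    weekly: pd.DataFrame,
    official: pd.DataFrame,
    tolerance: float = 0.01,
) -> ValidationReport:
    """Compare weekly sums per year and sex with official annual totals.

    Parameters
    ----------
    weekly
        Long table with ``year, week, sex, deaths`` (age groups summed or
        per-group; all rows of a (year, sex) are summed).  Use the
        all-ages series only.
    official
        Table with columns ``year, sex, deaths``.
    tolerance
        Maximum relative difference |sum_w D_w - D_official| / D_official
        for a pass (default 1%).
    """
    results: list[CheckResult] = []
    sums = weekly.groupby(["year", "sex"])["deaths"].sum()
    off = official.set_index(["year", "sex"])["deaths"]
    for (year, sex), total in sums.items():
        scope = f"year={int(year)}/sex={sex}"
        if (year, sex) not in off.index:
            results.append(
                CheckResult("official_annual", scope, "skipped", None, tolerance,
                            "no official annual total")
            )
            continue
        o = float(off.loc[(year, sex)])
        if o == 0:
            status = "pass" if total == 0 else "fail"
            results.append(
                CheckResult("official_annual", scope, status,
                            math.inf if total else 0.0, tolerance,
                            "official total is zero")
            )
            continue
        d = abs(float(total) - o) / o
        results.append(
            CheckResult(
                "official_annual", scope,
                "pass" if d <= tolerance else "fail",
                float(d), tolerance,
                "weekly sum vs official annual total",
            )
        )
    return ValidationReport(results)


def detect_outliers(
    history: pd.DataFrame | pd.Series,
    target: pd.Series | None = None,
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Flag weeks whose rate is implausible against the same-week history.

    For each week, a robust z-score is computed against that week's values
    across reference years: the centre is the week-specific median, and the
    scale is the MAD (scaled by 1.4826 for normal consistency) of the
    *pooled* residuals from the per-week medians across all weeks and
    years.  Pooling the scale is essential with the short reference
    windows typical here (4-6 years): a per-week MAD of so few values is
    so noisy that its z-scores have heavy tails and flag several percent
    of null weeks, while the pooled estimate keeps the null false-flag
    rate at the nominal level and is still robust to shock weeks.  A zero
    pooled MAD falls back to the pooled mean absolute deviation; if that
    is also zero nothing is flagged (identical history carries no
    dispersion information).  Flags are advisory and never alter the data.

    Parameters
    ----------
    history
        Years x weeks rate table (or (year, week)-indexed Series) of
        reference data, >= 2 years.
    target
        Week-indexed series to screen.  If omitted, each reference year is
        screened against the others (leave-self-in).
    threshold
        |z| above which a week is flagged.

    Returns
    -------
    pandas.DataFrame
        Columns ``year, week, value, zscore`` of flagged weeks (year is
        absent when *target* is given).
    """
    if isinstance(history, pd.Series):
        history = history.unstack(level=-1)
    if len(history.index) < 2:
        raise ValueError("outlier detection needs >= 2 reference years")

    med = history.median(axis=0)
    residuals = (history - med).to_numpy(dtype=float).ravel()
    residuals = residuals[np.isfinite(residuals)]
    pooled = float(np.median(np.abs(residuals))) * 1.4826
    if pooled == 0:
        pooled = float(np.mean(np.abs(residuals)))
    # small-sample corrections: residuals about the own-sample median are
    # deflated by ~sqrt((n-1)/n), and a new observation carries the
    # median's estimation variance (~pi/(2n) of sigma^2) on top of its own
    n = len(history.index)
    pooled *= math.sqrt(n / (n - 1)) * math.sqrt(1.0 + math.pi / (2 * n))
    scale = pd.Series(pooled, index=history.columns)

    def z(series: pd.Series) -> pd.Series:
        s = scale.reindex(series.index)
        ok = s > 0
        out = pd.Series(0.0, index=series.index)
        out[ok] = (series[ok] - med.reindex(series.index)[ok]) / s[ok]
        out[~ok] = 0.0
        return out

    rows = []
    if target is not None:
        zs = z(target.astype(float))
        for week, zv in zs.items():
            if abs(zv) > threshold:
                rows.append({"week": week, "value": float(target.loc[week]),
                             "zscore": float(zv)})
        return pd.DataFrame(rows, columns=["week", "value", "zscore"])

    for year in history.index:
        zs = z(history.loc[year].astype(float))
        for week, zv in zs.items():
            if abs(zv) > threshold:
                rows.append({"year": int(year), "week": week,
                             "value": float(history.loc[year, week]),
                             "zscore": float(zv)})
    return pd.DataFrame(rows, columns=["year", "week", "value", "zscore"])
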