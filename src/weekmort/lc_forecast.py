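"""Lee-Carter mortality forecasting and zero-migration exposure projection.

When the most recent year(s) of annual deaths and population exposures are
not yet observed, the pipeline extrapolates them.  The Lee-Carter model
decomposes the log death-rate surface as

    log m(x, t) = a_x + b_x * k_t,

with a_x the age pattern (row means of log rates), and (b_x, k_t) the
leading singular pair of the centered log-rate matrix under the usual
identification constraints sum(b_x) = 1 and sum(k_t) = 0.  The period index
k_t is forecast by a random walk with drift; only the central path is used
(the pipeline needs point exposures), with the innovation standard
deviation retained for reference.

Population exposures for forecast years are obtained by cohort bookkeeping
under zero migration: each age group loses deaths at its projected rate,
survivors age into the next group at the rate implied by a uniform
within-group age distribution (fraction 1/width per year), the open-ended
terminal group accumulates, and entry into the youngest group is held
constant at its last observed level.  The projected population is used
directly as the person-years exposure estimate.  Forecast annual deaths are
rates times projected exposures.

The default fit window starts in 2005 — a short, recent reference period so
the fit tracks current mortality change — and typical horizons are 1-4
years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LCParams",
    "fit_lee_carter",
    "forecast_rates",
    "project_population",
    "sensitivity_report",
    "DEFAULT_FIT_START",
]

DEFAULT_FIT_START = 2005


@dataclass
class LCParams:
    """Fitted Lee-Carter parameters.

    Attributes
    ----------
    ages : list
        Age-group labels, in the row order of the fitted matrix.
    a_x, b_x : ndarray
        Age pattern (log-rate intercepts) and age loadings; sum(b_x) = 1.
    k_t : ndarray
        Period index per fitted year; sum(k_t) = 0.
    drift : float
        Estimated annual change of k: (k_T - k_1) / (T - 1).
    sigma : float
        Standard deviation of the random-walk innovations k_t - k_{t-1} - drift.
    fit_years : list of int
        Contiguous years the model was fitted on.
    """

    ages: list
    a_x: np.ndarray
    b_x: np.ndarray
    k_t: np.ndarray
    drift: float
    sigma: float
    fit_years: list[int] = field(default_factory=list)


def fit_lee_carter(
    rates: pd.DataFrame,
    floor: float | None = None,
) -> LCParams:
    """Fit the Lee-Carter model to an ages x years matrix of death rates.

    Parameters
    ----------
    rates
        DataFrame with age groups as the row index and consecutive integer
        years as columns; entries are annual death rates (> 0 after
        flooring).
    floor
        Value substituted for zero rates before taking logs (a zero count
        makes the log undefined).  Default: for each age row, half the
        smallest positive rate in that row.  Every flooring event is
        logged.

    Returns
    -------
    LCParams

    Raises
    ------
    ValueError
        On fewer than 3 years or fewer than 2 ages, non-contiguous years,
        or an age row that is entirely zero (nothing to floor against).
    """
    years = [int(y) for y in rates.columns]
    if len(years) < 3:
        raise ValueError(f"Lee-Carter fit needs >= 3 years, got {len(years)}")
    if rates.shape[0] < 2:
        raise ValueError(f"Lee-Carter fit needs >= 2 age groups, got {rates.shape[0]}")
    if years != list(range(years[0], years[0] + len(years))):
        raise ValueError(f"fit years must be contiguous, got {years}")

    m = rates.to_numpy(dtype=float).copy()
    if (m < 0).any():
        raise ValueError("negative death rates")
    for i in range(m.shape[0]):
        row = m[i]
        if (row == 0).any():
            positive = row[row > 0]
            if positive.size == 0:
                raise ValueError(
                    f"age row {rates.index[i]!r} is entirely zero; cannot fit"
                )
            f = floor if floor is not None else positive.min() / 2.0
            nz = int((row == 0).sum())
            logger.info("floored %d zero rate(s) in age row %r at %g",
                        nz, rates.index[i], f)
            row[row == 0] = f

    logm = np.log(m)
    a_x = logm.mean(axis=1)
    centered = logm - a_x[:, None]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    b = u[:, 0]
    k = s[0] * vt[0, :]
    # identification: sum(b) = 1 (rescale k accordingly); sum(k) = 0 holds
    # already because rows were centered, but renormalize for exactness
    scale = b.sum()
    if abs(scale) < 1e-12:
        # degenerate (e.g. constant rates): no period signal
        b = np.full_like(b, 1.0 / len(b))
        k = np.zeros_like(k)
    else:
        b = b / scale
        k = k * scale
    k = k - k.mean()

    T = len(years)
    drift = (k[-1] - k[0]) / (T - 1)
    innov = np.diff(k) - drift
    sigma = float(np.std(innov, ddof=1)) if T > 2 else 0.0

    return LCParams(
        ages=list(rates.index),
        a_x=a_x,
        b_x=b,
        k_t=k,
        drift=float(drift),
        sigma=sigma,
        fit_years=years,
    )


def forecast_rates(params: LCParams, horizon: int) -> pd.DataFrame:
    """Central Lee-Carter rate forecast for *horizon* years past the fit.

    The period index follows a random walk with drift: k_{T+h} = k_T +
    h * drift; rates are exp(a_x + b_x * k).  Horizon 0 returns an empty
    frame.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    last_year = params.fit_years[-1]
    years = [last_year + h for h in range(1, horizon + 1)]
    k = params.k_t[-1] + params.drift * np.arange(1, horizon + 1)
    logm = params.a_x[:, None] + np.outer(params.b_x, k)
    return pd.DataFrame(np.exp(logm), index=params.ages, columns=years)


def _group_widths(groups: Sequence[tuple[float, float]]) -> np.ndarray:
    return np.array([hi - lo for lo, hi in groups], dtype=float)


def project_population(
    exposures: pd.Series,
    rates: pd.DataFrame,
    entry: float | None = None,
) -> pd.DataFrame:
    """Project age-group exposures forward under zero migration.

    Parameters
    ----------
    exposures
        Last observed person-years by age group, indexed by ``(start, end)``
        tuples covering all ages including the open-ended terminal group,
        in ascending age order.
    rates
        Forecast death rates from :func:`forecast_rates`; its row index
        must match the exposure index and its columns are the forecast
        years, whose count sets the horizon.
    entry
        Annual inflow into the youngest group (births reaching the group,
        in person-years).  Default: the youngest group's last observed
        exposure divided by its width, held constant over the horizon.

    Returns
    -------
    pandas.DataFrame
        Long table with columns ``year, age_start, age_end, deaths,
        exposure, source`` where ``source`` is ``"forecast"`` throughout.

    Notes
    -----
    Within-group survivorship uses exp(-m) per year with a uniform age
    distribution inside each group: each year a fraction 1/width of a
    group's survivors ages into the next group, the rest stay.  The open
    group has no exit except death.
    """
    groups = list(exposures.index)
    if not math.isinf(groups[-1][1]):
        raise ValueError("exposure index must end with the open-ended age group")
    widths = _group_widths(groups[:-1])
    pop = exposures.to_numpy(dtype=float).copy()
    if entry is None:
        entry = float(pop[0] / (groups[0][1] - groups[0][0]))

    records = []
    for year in rates.columns:
        m = rates[year].to_numpy(dtype=float)
        deaths = m * pop
        surv = pop * np.exp(-m)
        nxt = np.empty_like(pop)
        if len(groups) == 1:
            nxt[0] = surv[0] + entry
        else:
            stay = surv[:-1] * (1.0 - 1.0 / widths)
            advance = surv[:-1] / widths
            nxt[0] = stay[0] + entry
            nxt[1:-1] = stay[1:] + advance[:-1]
            nxt[-1] = surv[-1] + advance[-1]
        for (lo, hi), d, e in zip(groups, deaths, pop):
            records.append(
                {"year": int(year), "age_start": lo, "age_end": hi,
                 "deaths": float(d), "exposure": float(e), "source": "forecast"}
            )
        pop = nxt
    out = pd.DataFrame.from_records(records)
    if (out["exposure"] <= 0).any():
        raise ValueError("projected exposure fell to zero or below")
    return out


def sensitivity_report(
    rates: pd.DataFrame,
    start_years: Sequence[int],
    horizon: int = 1,
    default_start: int = DEFAULT_FIT_START,
) -> pd.DataFrame:
    """Sensitivity of forecast rates to the choice of fit-window start year.

    For each candidate start year, fit on [start, last observed year],
    forecast *horizon* years, and report the maximum relative difference of
    the final forecast year's rates against the default start year's
    forecast.  The result is a report, not an assertion — how much the
    choice matters depends on the data.

    Parameters
    ----------
    rates
        Ages x years annual death rates covering all candidate windows.
    start_years
        Candidate first years of the fit window (>= 2 of them for a
        non-empty comparison).

    Returns
    -------
    pandas.DataFrame
        Columns ``start_year, max_rel_change`` (empty if fewer than two
        candidates).
    """
    if len(start_years) < 2:
        return pd.DataFrame(columns=["start_year", "max_rel_change"])
    all_years = [int(y) for y in rates.columns]

    def final_forecast(start: int) -> np.ndarray:
        window = rates[[y for y in all_years if y >= start]]
        params = fit_lee_carter(window)
        return forecast_rates(params, horizon).iloc[:, -1].to_numpy()

    ref = final_forecast(default_start)
    rows = []
    for start in start_years:
        fc = final_forecast(int(start))
        rows.append(
            {"start_year": int(start),
             "max_rel_change": float(np.max(np.abs(fc - ref) / ref))}
        )
    return pd.DataFrame(rows)
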