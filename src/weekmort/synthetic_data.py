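"""Internally consistent synthetic weekly mortality data with known truth.

The generator emulates the statistical structure the pipeline assumes: a
population with stable age- and sex-specific annual death rates subject to
a secular log-linear trend, weekly counts with sinusoidal winter
seasonality and Poisson sampling noise, and optional short mortality shocks
(either additive deaths or a rate multiplier, by default concentrated at
old ages, as pandemic excess mortality is).  A companion coarsening step
degrades the fine-grained table the way real sources do — broad age bands,
combined sexes, a residual unknown-age count — so every harmonization
stage can be exercised against known ground truth.

Internal consistency is guaranteed by construction: the annual death
tables are the sums of the fine-grained weekly counts, and official annual
totals equal the annual table totals, so a generated dataset passes the
internal consistency checks exactly.

Default parameters describe a mid-sized developed country: ~5.8 million
people per sex, annual death rates rising from ~2 per 10,000 in childhood
to ~14% in the open 85+ group, male rates ~40% above female, a 1% annual
mortality decline, and a 15% relative winter peak in week 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from weekmort.harmonizer import STANDARD_AGE_GROUPS

__all__ = ["ShockSpec", "CoarsenSpec", "SimConfig", "SimData", "generate", "coarsen"]

WEEKS_PER_YEAR = 52

# default annual death rates per person by standard group
_DEFAULT_RATES = {
    "m": np.array([0.00025, 0.0025, 0.018, 0.055, 0.16]),
    "f": np.array([0.00018, 0.0015, 0.012, 0.040, 0.13]),
}
# default person-years by standard group, per sex
_DEFAULT_EXPOSURES = {
    "m": np.array([850_000.0, 3_300_000.0, 480_000.0, 260_000.0, 70_000.0]),
    "f": np.array([810_000.0, 3_250_000.0, 520_000.0, 330_000.0, 140_000.0]),
}


@dataclass
class ShockSpec:
    """A short mortality shock.

    ``mode="additive"``: *size* extra expected deaths spread uniformly over
    *weeks* and allocated over age groups by *age_weights* (default
    concentrated at old ages).  ``mode="multiplier"``: weekly expected
    counts in *weeks* are multiplied by *size* in the weighted groups.
    """

    year: int
    weeks: Sequence[int]
    size: float
    mode: str = "additive"
    age_weights: Sequence[float] | None = None  # default: (0, .05, .15, .3, .5)


@dataclass
class CoarsenSpec:
    """How a source country degrades the fine-grained table."""

    age_groups: Sequence[tuple[float, float]] | None = None  # None = keep fine
    combine_sex: bool = False
    unknown_fraction: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic country-series."""

    years: tuple[int, int] = (2015, 2020)
    age_groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS
    rates: dict[str, np.ndarray] = field(default_factory=lambda: dict(_DEFAULT_RATES))
    exposures: dict[str, np.ndarray] = field(
        default_factory=lambda: dict(_DEFAULT_EXPOSURES)
    )
    seasonal_amplitude: float = 0.15
    peak_week: int = 2
    trend: float = -0.01  # annual drift of log rates
    shock: ShockSpec | None = None
    noise: str = "poisson"  # or "none"
    pop_name: str = "SYN"
    seed: int = 0

    def validate(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("years span is empty")
        for sex in ("m", "f"):
            if sex not in self.rates or sex not in self.exposures:
                raise ValueError(f"rates/exposures must cover sex {sex!r}")
            if np.any(np.asarray(self.rates[sex]) <= 0):
                raise ValueError("annual rates must be > 0")
            if np.any(np.asarray(self.exposures[sex]) <= 0):
                raise ValueError("exposures must be > 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal amplitude must be in [0, 1)")


@dataclass
class SimData:
    """Output bundle of :func:`generate`.

    raw
        Fine-grained weekly table in the normalized raw layout
        (columns as returned by :func:`weekmort.raw_io.read_raw_deaths`).
    annual
        Long annual table (``year, sex, age_start, age_end, deaths,
        exposure, source``) whose deaths are the sums of ``raw``.
    official
        Official annual totals (``year, sex, deaths``), equal to the
        annual table totals.
    truth
        Dict with ``expected`` (the noise-free expected weekly counts in
        the same layout as ``raw``), ``shock_total`` (expected extra
        deaths injected), ``config``.
    """

    raw: pd.DataFrame
    annual: pd.DataFrame
    official: pd.DataFrame
    truth: dict


def _season_factors(amplitude: float, peak_week: int) -> np.ndarray:
    w = np.arange(1, WEEKS_PER_YEAR + 1)
    s = 1.0 + amplitude * np.cos(2 * np.pi * (w - peak_week) / WEEKS_PER_YEAR)
    return s / s.mean()  # exact mean 1 so annual totals are seasonality-free


def generate(config: SimConfig, seed: int | None = None) -> SimData:
    """Simulate one country-series under *config* (see module docstring).

    Weekly expected counts are ``annual_rate * exposure / 52 * seasonal
    factor``, plus/times the shock, then Poisson-sampled unless
    ``config.noise == "none"``.  A fixed seed makes the output
    bit-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups = list(config.age_groups)
    season = _season_factors(config.seasonal_amplitude, config.peak_week)

    shock = config.shock
    shock_weights = None
    if shock is not None:
        shock_weights = np.asarray(
            shock.age_weights if shock.age_weights is not None
            else [0.0, 0.05, 0.15, 0.30, 0.50][: len(groups)],
            dtype=float,
        )
        shock_weights = shock_weights / shock_weights.sum()

    rows = []
    y0 = config.years[0]
    shock_total_expected = 0.0
    for year in range(config.years[0], config.years[1] + 1):
        for sex in ("m", "f"):
            rates_y = np.asarray(config.rates[sex], dtype=float) * math.exp(
                config.trend * (year - y0)
            )
            expo = np.asarray(config.exposures[sex], dtype=float)
            base = rates_y * expo / WEEKS_PER_YEAR  # per-week expectation
            for wi, week in enumerate(range(1, WEEKS_PER_YEAR + 1)):
                mu = base * season[wi]
                if shock is not None and year == shock.year and week in shock.weeks:
                    if shock.mode == "additive":
                        extra = (shock.size / (2 * len(shock.weeks))) * shock_weights
                        shock_total_expected += extra.sum()
                        mu = mu + extra
                    elif shock.mode == "multiplier":
                        bump = mu * shock_weights * (shock.size - 1.0)
                        shock_total_expected += bump.sum()
                        mu = mu + bump
                    else:
                        raise ValueError(f"unknown shock mode {shock.mode!r}")
                for g, (lo, hi) in enumerate(groups):
                    rows.append((year, week, sex, lo, hi, mu[g]))

    expected = pd.DataFrame(
        rows, columns=["year", "week", "sex", "age_start", "age_end", "expected"]
    )
    if config.noise == "poisson":
        deaths = rng.poisson(expected["expected"].to_numpy()).astype(float)
    else:
        deaths = expected["expected"].to_numpy().copy()

    raw = pd.DataFrame(
        {
            "pop_name": config.pop_name,
            "area": "",
            "year": expected["year"],
            "week": expected["week"],
            "sex": expected["sex"],
            "age_start": expected["age_start"].astype(float),
            "age_interval": (expected["age_end"] - expected["age_start"]).astype(float),
            "data_type": "occurrence",
            "access": "O",
            "deaths": deaths,
        }
    )

    annual_deaths = (
        raw.groupby(["year", "sex", "age_start", "age_interval"], as_index=False)[
            "deaths"
        ].sum()
    )
    annual_rows = []
    for _, r in annual_deaths.iterrows():
        gi = [g[0] for g in groups].index(r["age_start"])
        annual_rows.append(
            {
                "year": int(r["year"]),
                "sex": r["sex"],
                "age_start": r["age_start"],
                "age_end": r["age_start"] + r["age_interval"],
                "deaths": float(r["deaths"]),
                "exposure": float(config.exposures[r["sex"]][gi]),
                "source": "observed",
            }
        )
    annual = pd.DataFrame(annual_rows)
    both = (
        annual.groupby(["year", "age_start", "age_end"], as_index=False)[
            ["deaths", "exposure"]
        ].sum()
    )
    both["sex"] = "b"
    both["source"] = "observed"
    annual = pd.concat([annual, both], ignore_index=True)

    official = annual.groupby(["year", "sex"], as_index=False)["deaths"].sum()

    return SimData(
        raw=raw,
        annual=annual,
        official=official,
        truth={
            "expected": expected,
            "shock_total": shock_total_expected,  # summed over sexes and weeks
            "config": config,
        },
    )


def coarsen(
    fine: pd.DataFrame,
    spec: CoarsenSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Degrade a fine-grained raw table the way a source country would.

    Broad-group sums (the spec groups must nest the fine groups), optional
    both-sex merge, and optional extraction of a fixed fraction of each
    cell's deaths into an unknown-age row per stratum.

    Raises
    ------
    ValueError
        If a fine group straddles two broad groups.
    """
    df = fine.copy()
    if spec.age_groups is not None:
        broad = list(spec.age_groups)

        def assign(row):
            lo, hi = row["age_start"], row["age_start"] + row["age_interval"]
            for b in broad:
                if b[0] <= lo and hi <= b[1]:
                    return b
            raise ValueError(
                f"fine group [{lo}, {hi}) does not nest in the coarsening groups"
            )

        assigned = df.apply(assign, axis=1)
        df["age_start"] = [b[0] for b in assigned]
        df["age_interval"] = [b[1] - b[0] for b in assigned]
        df = df.groupby(
            ["pop_name", "area", "year", "week", "sex", "age_start", "age_interval",
             "data_type", "access"],
            as_index=False,
        )["deaths"].sum()

    if spec.combine_sex:
        df["sex"] = "b"
        df = df.groupby(
            ["pop_name", "area", "year", "week", "sex", "age_start", "age_interval",
             "data_type", "access"],
            as_index=False,
        )["deaths"].sum()

    if spec.unknown_fraction > 0:
        if not spec.unknown_fraction < 1:
            raise ValueError("unknown_fraction must be in [0, 1)")
        moved = df["deaths"] * spec.unknown_fraction
        df = df.assign(deaths=df["deaths"] - moved)
        unk = df.copy()
        unk["deaths"] = moved
        unk = unk.groupby(
            ["pop_name", "area", "year", "week", "sex", "data_type", "access"],
            as_index=False,
        )["deaths"].sum()
        unk["age_start"] = np.nan
        unk["age_interval"] = np.nan
        df = pd.concat([df, unk[df.columns]], ignore_index=True)

    return df.reset_index(drop=True)[
        ["pop_name", "area", "year", "week", "sex", "age_start", "age_interval",
         "data_type", "access", "deaths"]
    ]
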