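"""End-to-end orchestration: raw weekly counts to harmonized rates and excess.

Processing starts from the collection of annual population exposures and
weekly death counts, then proceeds through a fixed stage order:

1. read and validate the raw weekly table;
2. enforce the 52-week statistical year (week 53 merged into week 52);
3. harmonize (unknown-age redistribution, age split, sex split);
4. for years lacking observed annual data, forecast annual deaths and
   exposures with Lee-Carter under zero migration and flag them;
5. compute person-week death rates;
6. optionally estimate weekly excess against a configured baseline;
7. run the consistency checks (report-only: validation failures are
   documented, never fixed, and never abort the run).

Every adjustment is visible in the Split/SplitSex/Forecast flags or in the
run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from weekmort import harmonizer, lc_forecast, quality_checks, rates_excess, raw_io
from weekmort.harmonizer import STANDARD_AGE_GROUPS
from weekmort.week_calendar import clamp_to_52

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stmf_wide"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    raw_path: str = ""
    annual_path: str = ""
    official_path: str = ""  # optional
    country_code: str = "SYN"
    target_groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS
    lc_fit_start: int = lc_forecast.DEFAULT_FIT_START
    baseline_method: str = "week_mean"
    reference_years: tuple[int, int] | None = None  # inclusive span
    target_year: int | None = None
    completeness_cutoff_week: int | None = None
    external_tolerance: float = 0.01
    week53_mode: str = "merge"
    output_path: str = "stmf_output.csv"
    excess_path: str = "excess.csv"
    report_path: str = "validation.jsonl"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "target_groups" in data:
            data["target_groups"] = [tuple(
                float("inf") if v in ("inf", "+") else float(v) for v in g
            ) for g in data["target_groups"]]
        if data.get("reference_years"):
            data["reference_years"] = tuple(data["reference_years"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["target_groups"] = [
            ["inf" if np.isinf(v) else v for v in g] for g in self.target_groups
        ]
        if self.reference_years is not None:
            data["reference_years"] = list(self.reference_years)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class PipelineResult:
    stmf: pd.DataFrame
    report: quality_checks.ValidationReport
    excess: dict[str, rates_excess.ExcessResult] = field(default_factory=dict)


def _annual_rate_matrix(annual: pd.DataFrame, sex: str,
                        groups: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Ages x years matrix of annual death rates for one sex."""
    sl = annual[annual["sex"] == sex]
    years = sorted(sl["year"].unique())
    mat = pd.DataFrame(index=pd.Index(list(groups), tupleize_cols=False),
                       columns=years, dtype=float)
    for year in years:
        d = harmonizer.annual_group_series(annual, year, sex, "deaths", groups)
        e = harmonizer.annual_group_series(annual, year, sex, "exposure", groups)
        mat[year] = (d / e).to_numpy()
    return mat


def extend_annual_with_forecast(
    annual: pd.DataFrame,
    needed_years: Sequence[int],
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
    fit_start: int = lc_forecast.DEFAULT_FIT_START,
) -> pd.DataFrame:
    """Append Lee-Carter forecast rows for years missing from *annual*.

    Per sex, fits on observed years >= *fit_start*, forecasts death rates,
    projects exposures under zero migration, and derives forecast deaths;
    both-sex rows are the sums of the sex-specific forecasts.  Appended
    rows carry ``source = "forecast"``.
    """
    observed_years = set(annual["year"].unique())
    missing = sorted(set(int(y) for y in needed_years) - observed_years)
    if not missing:
        return annual
    horizon = max(missing) - max(observed_years)
    if horizon < 1:
        raise ValueError(
            f"missing years {missing} lie inside the observed span; "
            "cannot forecast an interior gap"
        )
    logger.info("forecasting annual data for %s (horizon %d)", missing, horizon)

    per_sex: dict[str, pd.DataFrame] = {}
    for sex in ("m", "f"):
        rates = _annual_rate_matrix(annual, sex, groups)
        rates = rates[[y for y in rates.columns if y >= fit_start]]
        params = lc_forecast.fit_lee_carter(rates)
        fc_rates = lc_forecast.forecast_rates(params, horizon)
        last_year = max(observed_years)
        expo = harmonizer.annual_group_series(annual, last_year, sex, "exposure", groups)
        proj = lc_forecast.project_population(expo, fc_rates)
        proj["sex"] = sex
        per_sex[sex] = proj

    cols = ["year", "sex", "age_start", "age_end", "deaths", "exposure", "source"]
    fc = pd.concat([per_sex["m"], per_sex["f"]], ignore_index=True)[cols]
    both = fc.groupby(["year", "age_start", "age_end"], as_index=False)[
        ["deaths", "exposure"]].sum()
    both["sex"] = "b"
    both["source"] = "forecast"
    out = pd.concat([annual, fc, both[cols]], ignore_index=True)
    return out[out["year"].isin(observed_years | set(missing))].reset_index(drop=True)


def stmf_wide(
    harmonized: pd.DataFrame,
    annual: pd.DataFrame,
    country_code: str,
    groups: Sequence[tuple[float, float]] = STANDARD_AGE_GROUPS,
) -> pd.DataFrame:
    """Assemble the wide output table (counts, person-week rates, flags)."""
    rows = []
    dcols = raw_io.stmf_columns(groups)[4:4 + len(groups)]
    for (year, week, sex), grp in harmonized.groupby(["year", "week", "sex"]):
        grp = grp.set_index(
            pd.Index([(a, b) for a, b in zip(grp["age_start"], grp["age_end"])],
                     tupleize_cols=False)
        )
        expo = harmonizer.annual_group_series(annual, int(year), sex, "exposure", groups)
        counts = grp["deaths"].reindex(expo.index).fillna(0.0)
        rates = rates_excess.weekly_rate(counts.to_numpy(), expo.to_numpy())
        row = {
            "CountryCode": country_code, "Year": int(year), "Week": int(week),
            "Sex": sex,
        }
        for c, v in zip(dcols, counts.to_numpy()):
            row[c] = float(v)
        row["DTotal"] = float(counts.sum())
        for c, v in zip([f"R{c[1:]}" for c in dcols], rates):
            row[c] = float(v)
        row["RTotal"] = float(
            rates_excess.weekly_rate(counts.sum(), float(expo.sum()))
        )
        row["Split"] = int(grp["split"].max())
        row["SplitSex"] = int(grp["split_sex"].max())
        row["Forecast"] = int(grp["forecast"].max())
        rows.append(row)
    return pd.DataFrame(rows)[raw_io.stmf_columns(groups)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see module docstring for stage order."""
    groups = tuple(tuple(g) for g in config.target_groups)

    raw = raw_io.read_raw_deaths(config.raw_path) if isinstance(
        config.raw_path, (str, Path)) else config.raw_path
    annual = pd.read_csv(config.annual_path) if isinstance(
        config.annual_path, (str, Path)) and config.annual_path else config.annual_path

    raw = clamp_to_52(raw, value_columns=["deaths"], mode=config.week53_mode)

    needed_years = sorted(raw["year"].unique())
    annual = extend_annual_with_forecast(
        annual, needed_years, groups, config.lc_fit_start
    )

    harmonized = harmonizer.harmonize_table(raw, annual, groups)
    stmf = stmf_wide(harmonized, annual, config.country_code, groups)

    if config.output_path:
        raw_io.write_stmf_output(stmf, config.output_path, groups)
        logger.info("wrote %d harmonized records to %s", len(stmf), config.output_path)

    # validation (report-only)
    raw_totals = raw.groupby(["year", "week"])["deaths"].sum()
    report = quality_checks.check_internal(harmonized, raw_totals=raw_totals)
    if config.official_path:
        official = pd.read_csv(config.official_path) if isinstance(
            config.official_path, (str, Path)) else config.official_path
        weekly_b = harmonized[harmonized["sex"] == "b"]
        ext = quality_checks.check_external(
            weekly_b, official, tolerance=config.external_tolerance
        )
        report = quality_checks.ValidationReport(report.results + ext.results)
    if config.report_path:
        Path(config.report_path).write_text(report.to_json_lines() + "\n")
    for failure in report.failures():
        logger.warning("validation failure: %s @ %s", failure.check_id, failure.scope)

    # excess
    excess_results: dict[str, rates_excess.ExcessResult] = {}
    if config.reference_years and config.target_year:
        ref = list(range(config.reference_years[0], config.reference_years[1] + 1))
        for sex in ("m", "f", "b"):
            mask = stmf["Sex"] == sex
            hist = stmf[mask & stmf["Year"].isin(ref)].pivot_table(
                index="Year", columns="Week", values="RTotal"
            )
            obs = stmf[mask & (stmf["Year"] == config.target_year)].set_index(
                "Week")["RTotal"]
            if config.completeness_cutoff_week is not None:
                obs = obs[obs.index <= config.completeness_cutoff_week]
            expected = rates_excess.baseline(
                hist, config.baseline_method, ref, config.target_year
            ).reindex(obs.index)
            expo_all = harmonizer.annual_group_series(
                annual, config.target_year, sex, "exposure", groups
            ).sum()
            excess_results[sex] = rates_excess.excess(
                obs, expected, annual_exposure=float(expo_all),
                method=config.baseline_method, reference_years=ref,
            )
        if config.excess_path:
            frames = []
            for sex, res in excess_results.items():
                t = res.table.copy()
                t.insert(0, "Sex", sex)
                t.insert(0, "Year", config.target_year)
                frames.append(t.reset_index(names="Week"))
            pd.concat(frames, ignore_index=True).to_csv(
                config.excess_path, index=False, float_format="%.17g"
            )

    return PipelineResult(stmf=stmf, report=report, excess=excess_results)
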