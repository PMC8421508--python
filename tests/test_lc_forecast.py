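"""Lee-Carter fit/forecast: parameter recovery, constraints, projection."""

import math

import numpy as np
import pandas as pd
import pytest

from weekmort import lc_forecast as lc

AGES = [(0, 15), (15, 65), (65, 75), (75, 85), (85, math.inf)]
BASE_LOG_RATES = np.log([3e-4, 2e-3, 1.5e-2, 4.5e-2, 1.4e-1])


def make_rates(a, b, k, start_year=2005):
    years = list(range(start_year, start_year + len(k)))
    m = np.exp(np.asarray(a)[:, None] + np.outer(b, k))
    return pd.DataFrame(
        m, index=pd.Index(AGES[: len(a)], tupleize_cols=False), columns=years
    )


def constrained_bk(rng, n_ages, n_years):
    b = rng.random(n_ages)
    b = b / b.sum()
    k = rng.normal(0, 1, n_years)
    k = k - k.mean()
    return b, k


class TestFit:
    def test_noise_free_recovery(self):
        rng = np.random.default_rng(1)
        b, k = constrained_bk(rng, 5, 12)
        rates = make_rates(BASE_LOG_RATES, b, k)
        p = lc.fit_lee_carter(rates)
        assert np.abs(p.a_x - BASE_LOG_RATES).max() < 1e-8
        assert np.abs(p.b_x - b).max() < 1e-8
        assert np.abs(p.k_t - k).max() < 1e-8

    def test_constraints_after_fit(self):
        rng = np.random.default_rng(2)
        rates = make_rates(*((BASE_LOG_RATES,) + constrained_bk(rng, 5, 8)))
        p = lc.fit_lee_carter(rates)
        assert abs(p.b_x.sum() - 1) < 1e-10
        assert abs(p.k_t.sum()) < 1e-10

    def test_constant_rates_give_zero_k_and_drift(self):
        rates = make_rates(BASE_LOG_RATES, np.full(5, 0.2), np.zeros(6))
        p = lc.fit_lee_carter(rates)
        assert np.abs(p.k_t).max() == pytest.approx(0, abs=1e-12)
        assert p.drift == pytest.approx(0, abs=1e-12)

    def test_linear_k_gives_exact_drift(self):
        slope = -0.8
        k = slope * (np.arange(10) - 4.5)
        b = np.full(5, 0.2)
        p = lc.fit_lee_carter(make_rates(BASE_LOG_RATES, b, k))
        assert p.drift == pytest.approx(slope, rel=1e-10)
        assert p.sigma == pytest.approx(0, abs=1e-9)

    def test_refit_is_fixed_point(self):
        rng = np.random.default_rng(3)
        b, k = constrained_bk(rng, 5, 9)
        p1 = lc.fit_lee_carter(make_rates(BASE_LOG_RATES, b, k))
        regenerated = make_rates(p1.a_x, p1.b_x, p1.k_t)
        p2 = lc.fit_lee_carter(regenerated)
        np.testing.assert_allclose(p2.b_x, p1.b_x, atol=1e-9)
        np.testing.assert_allclose(p2.k_t, p1.k_t, atol=1e-9)

    def test_too_few_years_or_ages_rejected(self):
        rates = make_rates(BASE_LOG_RATES, np.full(5, 0.2), np.zeros(2))
        with pytest.raises(ValueError, match="3 years"):
            lc.fit_lee_carter(rates)
        rates1 = make_rates(BASE_LOG_RATES[:1], [1.0], np.zeros(5))
        with pytest.raises(ValueError, match="2 age"):
            lc.fit_lee_carter(rates1)

    def test_zero_rates_floored_all_zero_row_rejected(self):
        rates = make_rates(BASE_LOG_RATES, np.full(5, 0.2), np.zeros(5))
        rates.iloc[0, 2] = 0.0
        p = lc.fit_lee_carter(rates)  # flooring succeeds
        assert np.isfinite(p.a_x).all()
        rates.iloc[0, :] = 0.0
        with pytest.raises(ValueError, match="entirely zero"):
            lc.fit_lee_carter(rates)


class TestForecast:
    def test_linear_history_continues_the_line(self):
        slope = -0.5
        k = slope * (np.arange(8) - 3.5)
        b = np.full(5, 0.2)
        p = lc.fit_lee_carter(make_rates(BASE_LOG_RATES, b, k))
        fc = lc.forecast_rates(p, 3)
        for h in range(1, 4):
            expected = np.exp(BASE_LOG_RATES + b * (k[-1] + h * slope))
            np.testing.assert_allclose(fc.iloc[:, h - 1].to_numpy(), expected,
                                       rtol=1e-10)

    def test_zero_loading_age_is_constant(self):
        b = np.array([0.0, 0.25, 0.25, 0.25, 0.25])
        k = np.array([2.0, 1.0, 0.0, -1.0, -2.0])
        p = lc.fit_lee_carter(make_rates(BASE_LOG_RATES, b, k))
        fc = lc.forecast_rates(p, 4)
        np.testing.assert_allclose(
            fc.iloc[0].to_numpy(), np.exp(p.a_x[0]), rtol=1e-9
        )

    def test_zero_horizon_empty(self):
        p = lc.fit_lee_carter(make_rates(BASE_LOG_RATES, np.full(5, .2), np.zeros(5)))
        assert lc.forecast_rates(p, 0).empty

    def test_recovery_under_poisson_noise(self):
        """Simulate 15 years from known LC + drift at exposure 1e5, fit on
        the first 12, forecast 3: median relative rate error < 5%."""
        rng = np.random.default_rng(2024)
        drift = -0.15
        b = np.array([0.1, 0.2, 0.25, 0.25, 0.2])
        errors = []
        for _ in range(20):
            k = drift * np.arange(15) + rng.normal(0, 0.03, 15)
            true = np.exp(BASE_LOG_RATES[:, None] + np.outer(b, k - k.mean()))
            exposure = 1e5
            deaths = rng.poisson(true * exposure)
            obs = pd.DataFrame(
                deaths / exposure,
                index=pd.Index(AGES, tupleize_cols=False),
                columns=range(2005, 2020),
            )
            p = lc.fit_lee_carter(obs.iloc[:, :12])
            fc = lc.forecast_rates(p, 3)
            errors.append(np.abs(fc.to_numpy() / true[:, 12:] - 1.0).ravel())
        assert np.median(np.concatenate(errors)) < 0.05


class TestProjectPopulation:
    def exposures(self):
        return pd.Series(
            [8e5, 3.3e6, 4.8e5, 2.6e5, 7e4],
            index=pd.Index(AGES, tupleize_cols=False),
        )

    def test_zero_mortality_conserves_cohorts(self):
        expo = self.exposures()
        rates = pd.DataFrame(
            0.0, index=expo.index, columns=[2021, 2022]
        )
        proj = lc.project_population(expo, rates)
        y1 = proj[proj.year == 2021]
        assert (y1["deaths"] == 0).all()
        # total population conserved plus constant entry inflow
        y2 = proj[proj.year == 2022]
        entry = expo.iloc[0] / 15
        assert y2["exposure"].sum() == pytest.approx(expo.sum() + entry)

    def test_infinite_mortality_empties_group(self):
        expo = self.exposures()
        rates = pd.DataFrame(0.001, index=expo.index, columns=[2021, 2022])
        rates.loc[[(65, 75)], 2021] = 50.0  # essentially nobody survives
        proj = lc.project_population(expo, rates)
        y2 = proj[(proj.year == 2022) & (proj.age_start == 75)]
        # inflow into 75-84 comes only from the emptied 65-74 group
        stay = expo.loc[[(75, 85)]].iloc[0] * math.exp(-0.001) * (1 - 0.1)
        assert y2["exposure"].iloc[0] == pytest.approx(stay, rel=1e-6)

    def test_single_open_group_closed_form(self):
        expo = pd.Series([1000.0], index=pd.Index([(0, math.inf)], tupleize_cols=False))
        rates = pd.DataFrame(0.1, index=expo.index, columns=[2021, 2022])
        proj = lc.project_population(expo, rates)
        assert proj[proj.year == 2021]["deaths"].iloc[0] == pytest.approx(100.0)
        assert proj[proj.year == 2022]["exposure"].iloc[0] == pytest.approx(
            1000.0 * math.exp(-0.1)
        )

    def test_deaths_equal_rates_times_exposures(self):
        expo = self.exposures()
        rng = np.random.default_rng(5)
        rates = pd.DataFrame(
            rng.uniform(0.001, 0.1, (5, 3)), index=expo.index,
            columns=[2021, 2022, 2023],
        )
        proj = lc.project_population(expo, rates)
        for _, row in proj.iterrows():
            m = rates.loc[[(row["age_start"], row["age_end"])], row["year"]].iloc[0]
            assert row["deaths"] == pytest.approx(m * row["exposure"], rel=1e-12)

    def test_missing_open_group_rejected(self):
        expo = pd.Series(
            [1.0, 2.0], index=pd.Index([(0, 15), (15, 65)], tupleize_cols=False)
        )
        rates = pd.DataFrame(0.01, index=expo.index, columns=[2021])
        with pytest.raises(ValueError, match="open-ended"):
            lc.project_population(expo, rates)


class TestSensitivity:
    def test_identical_start_gives_zero_change(self):
        rng = np.random.default_rng(8)
        b, k = constrained_bk(rng, 5, 16)
        rates = make_rates(BASE_LOG_RATES, b, k, start_year=2000)
        rep = lc.sensitivity_report(rates, [2005, 2005], default_start=2005)
        assert (rep["max_rel_change"] == 0).all()

    def test_stable_series_is_insensitive_to_start_year(self):
        k = -0.1 * (np.arange(16) - 7.5)
        rates = make_rates(BASE_LOG_RATES, np.full(5, 0.2), k, start_year=2000)
        rep = lc.sensitivity_report(rates, list(range(2000, 2011)),
                                    default_start=2005)
        assert rep["max_rel_change"].max() < 0.005

    def test_single_start_year_empty(self):
        rates = make_rates(BASE_LOG_RATES, np.full(5, 0.2), np.zeros(6))
        assert lc.sensitivity_report(rates, [2005]).empty
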