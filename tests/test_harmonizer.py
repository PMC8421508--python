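"""Proportional splitting: spec'd examples, conservation, idempotence, order."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from weekmort import harmonizer as hz
from weekmort.harmonizer import (
    STANDARD_AGE_GROUPS,
    HarmonizationError,
    age_group_label,
    parse_age_group_label,
    redistribute_unknown_age,
    split_age_groups,
    split_sex,
)

from conftest import group_series


def test_age_group_labels_round_trip():
    for g in STANDARD_AGE_GROUPS:
        assert parse_age_group_label(age_group_label(g)) == g
    assert age_group_label((85, math.inf)) == "85+"
    assert age_group_label((0, 15)) == "0-14"


class TestRedistributeUnknownAge:
    def test_proportional_allocation(self):
        out = redistribute_unknown_age(group_series([90, 10]), 10)
        assert out.tolist() == [99.0, 11.0]

    def test_zero_unknown_is_identity(self):
        known = group_series([90, 10])
        assert redistribute_unknown_age(known, 0).tolist() == [90.0, 10.0]

    def test_annual_fallback_when_week_is_empty(self):
        out = redistribute_unknown_age(
            group_series([0, 0]), 8, annual_distribution=group_series([50, 50])
        )
        assert out.tolist() == [4.0, 4.0]

    def test_error_when_no_distribution_available(self):
        with pytest.raises(HarmonizationError):
            redistribute_unknown_age(group_series([0, 0]), 8)
        with pytest.raises(HarmonizationError):
            redistribute_unknown_age(
                group_series([0, 0]), 8, annual_distribution=group_series([0, 0])
            )


OLD_GROUPS = [(65, 75), (75, 85), (85, math.inf)]


class TestSplitAgeGroups:
    def test_broad_old_age_split(self):
        weekly = group_series([100], [(65, math.inf)])
        annual = group_series([300, 500, 200], OLD_GROUPS)
        out, flag = split_age_groups(weekly, annual, OLD_GROUPS)
        assert out.tolist() == [30.0, 50.0, 20.0]
        assert flag == 1

    def test_already_standard_is_identity_with_flag_zero(self):
        weekly = group_series([3, 5, 2], OLD_GROUPS)
        annual = group_series([300, 500, 200], OLD_GROUPS)
        out, flag = split_age_groups(weekly, annual, OLD_GROUPS)
        assert out.tolist() == [3.0, 5.0, 2.0]
        assert flag == 0

    def test_straddling_target_rejected(self):
        weekly = group_series([10, 10], [(0, 50), (50, math.inf)])
        annual = group_series([1, 1, 1, 1, 1], STANDARD_AGE_GROUPS)
        with pytest.raises(HarmonizationError, match="nest"):
            split_age_groups(weekly, annual, STANDARD_AGE_GROUPS)

    def test_zero_annual_denominator(self):
        weekly = group_series([10], [(65, math.inf)])
        annual = group_series([0, 0, 0], OLD_GROUPS)
        with pytest.raises(HarmonizationError, match="zero"):
            split_age_groups(weekly, annual, OLD_GROUPS)
        # but a zero weekly count yields zeros, not an error
        out, _ = split_age_groups(
            group_series([0], [(65, math.inf)]), annual, OLD_GROUPS
        )
        assert out.tolist() == [0.0, 0.0, 0.0]

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        weekly=st.lists(st.floats(0, 1e6), min_size=2, max_size=2),
        annual=st.lists(st.floats(0.1, 1e7), min_size=5, max_size=5),
    )
    def test_conservation_property(self, weekly, annual):
        """Per-source-interval sums of the split equal the source counts."""
        src = [(0, 65), (65, math.inf)]
        w = group_series(weekly, src)
        a = group_series(annual, STANDARD_AGE_GROUPS)
        out, _ = split_age_groups(w, a, STANDARD_AGE_GROUPS)
        total = out.sum()
        assert total == pytest.approx(w.sum(), rel=1e-9, abs=1e-12)
        assert out.iloc[:2].sum() == pytest.approx(weekly[0], rel=1e-9, abs=1e-12)
        assert out.iloc[2:].sum() == pytest.approx(weekly[1], rel=1e-9, abs=1e-12)


class TestSplitSex:
    def test_annual_sex_ratio_applied(self):
        weekly = group_series([100], [(75, 85)])
        male = group_series([4000], [(75, 85)])
        total = group_series([10000], [(75, 85)])
        m, f, flag = split_sex(weekly, male, total)
        assert m.tolist() == [40.0]
        assert f.tolist() == [60.0]
        assert flag == 1

    def test_zero_weekly_count(self):
        m, f, _ = split_sex(
            group_series([0], [(0, 15)]),
            group_series([5], [(0, 15)]),
            group_series([9], [(0, 15)]),
        )
        assert (m.tolist(), f.tolist()) == ([0.0], [0.0])

    def test_zero_annual_total_with_weekly_deaths(self):
        with pytest.raises(HarmonizationError, match="zero"):
            split_sex(
                group_series([5], [(0, 15)]),
                group_series([0], [(0, 15)]),
                group_series([0], [(0, 15)]),
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        weekly=st.lists(st.floats(0, 1e5), min_size=5, max_size=5),
        male_share=st.lists(st.floats(0.01, 0.99), min_size=5, max_size=5),
    )
    def test_sexes_sum_to_total(self, weekly, male_share):
        w = group_series(weekly, STANDARD_AGE_GROUPS)
        tot = group_series([1000] * 5, STANDARD_AGE_GROUPS)
        male = tot * male_share
        m, f, _ = split_sex(w, male, tot)
        np.testing.assert_allclose((m + f).to_numpy(), w.to_numpy(), rtol=1e-12)


class TestOrderIndependence:
    def test_redistribute_then_split_equals_split_then_redistribute(self):
        """When the annual fallback is not triggered, unknown-age
        redistribution and age splitting commute (both are proportional)."""
        rng = np.random.default_rng(7)
        src = [(0, 65), (65, math.inf)]
        for _ in range(50):
            weekly = group_series(rng.uniform(1, 100, 2), src)
            unknown = float(rng.uniform(0, 20))
            annual = group_series(rng.uniform(10, 1000, 5), STANDARD_AGE_GROUPS)

            a = redistribute_unknown_age(weekly, unknown)
            out1, _ = split_age_groups(a, annual, STANDARD_AGE_GROUPS)

            out2, _ = split_age_groups(weekly, annual, STANDARD_AGE_GROUPS)
            out2 = redistribute_unknown_age(out2, unknown)

            np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), rtol=1e-9)


class TestHarmonizeTable:
    def test_fine_input_passes_through_with_zero_flags(self, noise_free_sim):
        harm = hz.harmonize_table(noise_free_sim.raw, noise_free_sim.annual)
        assert harm["split"].max() == 0
        assert harm["split_sex"].max() == 0
        assert harm["forecast"].max() == 0
        m = harm[harm.sex == "m"].set_index(["year", "week", "age_start"])["deaths"]
        truth = noise_free_sim.raw[noise_free_sim.raw.sex == "m"].set_index(
            ["year", "week", "age_start"]
        )["deaths"]
        np.testing.assert_allclose(
            m.to_numpy(), truth.reindex(m.index).to_numpy(), rtol=1e-12
        )

    def test_conservation_through_full_harmonization(self, noisy_sim):
        from weekmort.synthetic_data import CoarsenSpec, coarsen

        spec = CoarsenSpec(
            age_groups=[(0, 65), (65, math.inf)],
            combine_sex=True,
            unknown_fraction=0.01,
        )
        coarse = coarsen(noisy_sim.raw, spec)
        harm = hz.harmonize_table(coarse, noisy_sim.annual)
        out_totals = (
            harm[harm.sex == "b"].groupby(["year", "week"])["deaths"].sum()
        )
        in_totals = coarse.groupby(["year", "week"])["deaths"].sum()
        np.testing.assert_allclose(
            out_totals.to_numpy(), in_totals.reindex(out_totals.index).to_numpy(),
            rtol=1e-9,
        )
        assert harm["split"].min() == 1  # year-level flags
        assert harm["split_sex"].min() == 1
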