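import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pondpredict import colwell, synthetic
from pondpredict.colwell import (
    EXCLUDED,
    ContingencyTable,
    build_table,
    colwell_metrics,
    assign_state,
    model_specs,
    run_discrete_model,
)
from pondpredict.errors import EstimationError, InputError
from pondpredict.timeseries import PondSeries

from conftest import make_obs

SPECS = model_specs()


def oracle_metrics(counts, base=math.e):
    """Independent brute-force entropy computation, plain Python loops."""
    counts = [[float(c) for c in row] for row in counts]
    s = len(counts)
    n_cols = len(counts[0])
    z = sum(sum(row) for row in counts)

    def plogp(p):
        return -p * math.log(p, base) if p > 0 else 0.0

    hx = sum(plogp(sum(counts[i][j] for i in range(s)) / z) for j in range(n_cols))
    hy = sum(plogp(sum(counts[i][j] for j in range(n_cols)) / z) for i in range(s))
    hxy = sum(plogp(counts[i][j] / z) for i in range(s) for j in range(n_cols))
    log_s = math.log(s, base)
    return (1 - hy / log_s,
            (hx + hy - hxy) / log_s,
            1 - (hxy - hx) / log_s)


class TestAssignState:
    def test_an_below_neighborhood(self):
        # mean 100, neighborhood 0.7 -> s1 below 30
        assert assign_state(20, 20, SPECS["COL_ANa"], 100.0) == 0

    def test_an_boundaries_belong_to_middle(self):
        # dyadic neighborhood 0.5 makes the break values exact floats
        spec = model_specs(neighborhood=0.5)["COL_ANa"]
        assert assign_state(50, 50, spec, 100.0) == 1
        assert assign_state(150, 150, spec, 100.0) == 1
        assert assign_state(150.0001, 150.0001, spec, 100.0) == 2
        assert assign_state(49.9999, 49.9999, spec, 100.0) == 0

    def test_maxlin_middle(self):
        assert assign_state(150, 150, SPECS["COL_MAXlin"], 300.0) == 1

    def test_maxg_breaks(self):
        assert assign_state(70, 70, SPECS["COL_MAXg"], 300.0) == 0
        assert assign_state(100, 100, SPECS["COL_MAXg"], 300.0) == 1
        assert assign_state(200, 200, SPECS["COL_MAXg"], 300.0) == 2

    def test_cloud_interval_excludes_wd(self):
        # dry by area, possibly wet by area_max -> state uncertain
        assert assign_state(0.0, 900.0, SPECS["COL_wd"], None) is EXCLUDED

    def test_cloud_interval_safe_when_same_state(self):
        assert assign_state(40, 60, SPECS["COL_ANa"], 100.0) == 1

    def test_reference_required(self):
        with pytest.raises(InputError):
            assign_state(10, 10, SPECS["COL_ANa"], None)
        with pytest.raises(InputError):
            assign_state(10, 10, SPECS["COL_MAXlin"], 0.0)


def yearly_series(state_areas, years=2):
    """One observation per month per year with the given area by month."""
    obs = []
    for y in range(years):
        for m, area in enumerate(state_areas, start=1):
            a = area(y) if callable(area) else area
            obs.append(make_obs(date=f"{2000 + y}-{m:02d}-15", area=a))
    return PondSeries(1, obs)


class TestBuildTable:
    def test_always_wet_two_years(self):
        series = yearly_series([50.0] * 12, years=2)
        table = build_table(series, SPECS["COL_wd"])
        np.testing.assert_array_equal(table.counts[1], np.full(12, 2))
        np.testing.assert_array_equal(table.counts[0], np.zeros(12))

    def test_alternating_wet_dry_years(self):
        series = yearly_series([lambda y: 50.0 if y % 2 == 0 else 0.0] * 12, years=2)
        table = build_table(series, SPECS["COL_wd"])
        np.testing.assert_array_equal(table.counts, np.ones((2, 12)))

    def test_known_schedule_tally(self):
        # 27 years, wet Jan-Jun, dry Jul-Dec
        series = yearly_series([lambda y: 80.0] * 6 + [lambda y: 0.0] * 6, years=27)
        table = build_table(series, SPECS["COL_wd"])
        np.testing.assert_array_equal(table.counts[1], [27] * 6 + [0] * 6)
        np.testing.assert_array_equal(table.counts[0], [0] * 6 + [27] * 6)

    def test_dry_months_dropped_for_anw(self):
        series = yearly_series([100.0] * 6 + [0.0] * 6, years=3)
        table = build_table(series, SPECS["COL_ANw"], reference_value=100.0)
        assert table.counts[:, 6:].sum() == 0
        assert table.total == 18

    def test_all_excluded_raises(self):
        obs = [make_obs(date="2000-01-15", area=0.0, area_max=900.0, cloud=0.5)]
        with pytest.raises(EstimationError):
            build_table(PondSeries(1, obs), SPECS["COL_wd"])


class TestColwellMetrics:
    def test_single_state_fully_constant(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[1] = 5
        res = colwell_metrics(ContingencyTable(counts))
        assert res.constancy == pytest.approx(1.0, abs=1e-12)
        assert res.contingency == pytest.approx(0.0, abs=1e-12)
        assert res.predictability == pytest.approx(1.0, abs=1e-12)

    def test_uniform_table_zero_predictability(self):
        res = colwell_metrics(ContingencyTable(np.full((3, 12), 4)))
        assert res.predictability == pytest.approx(0.0, abs=1e-12)

    def test_perfect_seasonality(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, :6] = 10
        counts[1, 6:] = 10
        res = colwell_metrics(ContingencyTable(counts))
        assert res.constancy == pytest.approx(0.0, abs=1e-12)
        assert res.contingency == pytest.approx(1.0, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            colwell_metrics(ContingencyTable(np.zeros((2, 12), dtype=int)))

    def test_oracle_equivalence_random_tables(self, rng):
        for _ in range(100):
            s = rng.choice([2, 3])
            counts = rng.integers(0, 31, (s, 12))
            if counts.sum() == 0:
                counts[0, 0] = 1
            res = colwell_metrics(ContingencyTable(counts))
            c, m, p = oracle_metrics(counts)
            assert res.constancy == pytest.approx(c, abs=1e-10)
            assert res.contingency == pytest.approx(m, abs=1e-10)
            assert res.predictability == pytest.approx(p, abs=1e-10)

    def test_log_base_invariance(self, rng):
        counts = rng.integers(0, 20, (3, 12))
        counts[0, 0] += 1
        nat = oracle_metrics(counts, base=math.e)
        two = oracle_metrics(counts, base=2.0)
        np.testing.assert_allclose(nat, two, atol=1e-12)

    @given(arrays(np.int64, (3, 12), elements=st.integers(0, 30)))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_additivity_fuzz(self, counts):
        if counts.sum() == 0:
            counts[1, 5] = 1
        res = colwell_metrics(ContingencyTable(counts))
        assert 0.0 <= res.constancy <= 1.0
        assert 0.0 <= res.contingency <= 1.0
        assert 0.0 <= res.predictability <= 1.0
        assert abs(res.predictability - (res.constancy + res.contingency)) <= 1e-12


class TestRunDiscreteModel:
    def test_never_dry_wd_is_one(self, never_dry_series):
        est = run_discrete_model(never_dry_series, "COL_wd")
        assert est.predictability == pytest.approx(1.0, abs=1e-12)

    def test_all_dry_wd_is_one(self):
        series = yearly_series([0.0] * 12, years=3)
        est = run_discrete_model(series, "COL_wd")
        assert est.predictability == pytest.approx(1.0, abs=1e-12)

    def test_unknown_model_rejected(self, never_dry_series):
        with pytest.raises(InputError):
            run_discrete_model(never_dry_series, "COL_nope")

    def test_uniform_bins_low_predictability(self, rng):
        # Areas i.i.d. uniform across the three MAXlin bins, month-independent.
        obs = []
        for y in range(60):
            for m in range(1, 13):
                obs.append(make_obs(date=f"{1900 + y}-{m:02d}-10",
                                    area=float(rng.uniform(0, 300))))
        est = run_discrete_model(PondSeries(1, obs), "COL_MAXlin")
        assert est.predictability < 0.1

    def test_year_permutation_invariance(self, seasonal_series):
        # Remap years: reverse their order; P must be unchanged for all models.
        years = sorted({o.date.year for o in seasonal_series.observations})
        remap = dict(zip(years, reversed(years)))
        def shift(date):
            day = 28 if (date.month == 2 and date.day == 29) else date.day
            return date.replace(year=remap[date.year], day=day)

        swapped = PondSeries(seasonal_series.pond_id, [
            make_obs(o.pond_id, shift(o.date).isoformat(),
                     o.area, o.area_max, o.cloud_fraction)
            for o in seasonal_series.observations
        ])
        for name in SPECS:
            a = run_discrete_model(seasonal_series, name).predictability
            b = run_discrete_model(swapped, name).predictability
            assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("name", sorted(SPECS))
    def test_scale_invariance(self, seasonal_series, name):
        base = run_discrete_model(seasonal_series, name)
        scaled = run_discrete_model(seasonal_series.scaled(1000.0), name)
        assert scaled.predictability == pytest.approx(base.predictability, abs=1e-12)

    def test_strong_seasonality_high_contingency(self, seasonal_series):
        est = run_discrete_model(seasonal_series, "COL_wd")
        assert est.contingency > 0.8
        assert est.predictability > 0.9

    def test_components_sum(self, seasonal_series):
        for name in SPECS:
            est = run_discrete_model(seasonal_series, name)
            assert est.predictability == pytest.approx(
                est.constancy + est.contingency, abs=1e-12
            )


def test_interval_unsafe_months_are_excluded():
    # Partial clouds that could flip the wd state must not be tabulated.
    obs = [make_obs(date="2000-01-15", area=0.0, area_max=1800.0, cloud=0.5),
           make_obs(date="2000-02-15", area=100.0)]
    table = build_table(PondSeries(1, obs), SPECS["COL_wd"])
    assert table.total == 1
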