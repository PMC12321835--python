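"""Daily allocation, cluster weight accumulation, yield, and the season loop."""

import datetime as dt

import numpy as np
import pytest

from strawsim import (
    EnvironmentSeries,
    FloweringSchedule,
    InputError,
    LeafAreaSeries,
    ModelParameters,
    allocate_to_clusters,
    fruit_partition_fraction,
    monthly_yield,
    simulate_season,
    update_cluster_weights,
    yield_per_area,
)

D0 = dt.date(2021, 9, 18)


class TestFruitPartitionFraction:
    @pytest.mark.parametrize(
        "gs,vs,expected",
        [
            (0.2, 0.2, 0.5),
            (0.0, 0.5, 0.0),
            (0.3432, 0.01092, 0.3432 / 0.35412),
            (0.0, 0.0, 0.0),  # no sinks at all: convention AF = 0
        ],
    )
    def test_values(self, gs, vs, expected):
        assert fruit_partition_fraction(gs, vs) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            fruit_partition_fraction(-0.1, 0.2)


class TestAllocateToClusters:
    def test_equal_shares(self):
        dmf = allocate_to_clusters(14.1, 0.8, [0.5, 0.5])
        assert dmf == pytest.approx([0.8, 0.8], rel=1e-12)

    def test_zero_total_increment(self):
        assert np.all(allocate_to_clusters(14.1, 0.8, [0.0, 0.0]) == 0.0)

    def test_single_cluster_gets_everything(self):
        dmf = allocate_to_clusters(14.1, 0.8, [0.37])
        assert dmf[0] == pytest.approx(14.1 / 7.05 * 0.8, rel=1e-12)

    def test_sum_matches_fruit_share_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            drfg = rng.uniform(0, 2, rng.integers(1, 6))
            ddm, af = rng.uniform(0, 20), rng.uniform(0, 1)
            dmf = allocate_to_clusters(ddm, af, drfg)
            assert dmf.sum() == pytest.approx(ddm / 7.05 * af, rel=1e-12)


class TestClusterWeights:
    def test_running_sum(self):
        df = np.zeros(1)
        for dmf in (0.5, 0.5, 1.0):
            df, ff = update_cluster_weights(df, [dmf], 0.10)
        assert df[0] == pytest.approx(2.0)
        assert ff[0] == pytest.approx(20.0)

    def test_fresh_weight_conversion(self):
        df, ff = update_cluster_weights([2.0], [0.5], 0.10)
        assert ff[0] == pytest.approx(25.0)

    def test_zero_allocation_leaves_df_unchanged(self):
        df, _ = update_cluster_weights([1.7], [0.0], 0.10)
        assert df[0] == 1.7


class TestYieldPerArea:
    def test_hand_value(self):
        assert yield_per_area([25.0, 15.0, 5.0], 7.05) == pytest.approx(0.31725)

    def test_no_clusters(self):
        assert yield_per_area([], 7.05) == 0.0

    def test_linear_in_density(self):
        assert yield_per_area([30.0], 14.10) == pytest.approx(
            2 * yield_per_area([30.0], 7.05)
        )


def _uniform_inputs(n_days=120, temp=15.0, sr=5.0, anthesis_dats=(55,), lai=2.0):
    dates = [D0 + dt.timedelta(days=i) for i in range(n_days)]
    env = EnvironmentSeries(dates, [temp] * n_days, [sr] * n_days)
    flowering = FloweringSchedule(
        [D0 + dt.timedelta(days=d) for d in anthesis_dats]
    )
    la = LeafAreaSeries(mode="lai", dates=[dates[0], dates[-1]], values=np.array([lai, lai]))
    return env, flowering, la


class TestSimulateSeason:
    def test_zero_radiation_no_growth(self):
        env, fl, la = _uniform_inputs(sr=0.0)
        res = simulate_season(env, fl, la)
        assert all(s.tdm == pytest.approx(19.9) for s in res.days)
        assert res.final.y == 0.0

    def test_no_anthesis_no_yield(self):
        dates = [D0 + dt.timedelta(days=i) for i in range(60)]
        env = EnvironmentSeries(dates, [15.0] * 60, [5.0] * 60)
        la = LeafAreaSeries(mode="lai", dates=[dates[0]], values=np.array([2.0]))
        res = simulate_season(env, FloweringSchedule([]), la)
        assert all(s.af == 0.0 for s in res.days)
        assert res.final.y == 0.0
        assert res.final.tdm > 19.9

    def test_anthesis_outside_window_rejected(self):
        env, _, la = _uniform_inputs(n_days=40)
        late = FloweringSchedule([D0 + dt.timedelta(days=55)])
        with pytest.raises(InputError):
            simulate_season(env, late, la)

    def test_deterministic(self, default_scenario):
        env, fl, la = default_scenario
        a = simulate_season(env, fl, la)
        b = simulate_season(env, fl, la)
        assert a.to_frame().equals(b.to_frame())

    def test_default_season_magnitudes(self, default_result):
        """Order of magnitude of a forcing-culture season: a few hundred grams
        of dry matter per m^2 and a few kg of fruit fresh weight per m^2."""
        assert 400.0 < default_result.final.tdm < 900.0
        assert 1.0 < default_result.final.y < 4.0

    def test_default_season_pinned_regression(self, default_result):
        """Frozen trajectory endpoint of the default scenario (seed 0)."""
        assert default_result.final.tdm == pytest.approx(472.6141837355364, rel=1e-9)
        assert default_result.final.y == pytest.approx(3.5159368321313034, rel=1e-9)

    def test_daily_conservation(self, default_result):
        """Every day, cluster allocations sum to the fruit share of that day's
        per-plant dry matter; the vegetative share is the complement."""
        pd_ = ModelParameters().pd
        for s in default_result.days:
            target = s.af * s.ddm / pd_
            if sum(s.dmf) > 0 or target > 0:
                assert sum(s.dmf) == pytest.approx(target, rel=1e-12)

    def test_monotone_state(self, default_result):
        days = default_result.days
        for a, b in zip(days, days[1:]):
            assert b.tdm >= a.tdm
            assert b.y >= a.y
            assert all(d1 >= d0 for d0, d1 in zip(a.df, b.df))
            assert 0.0 <= b.af <= 1.0

    def test_yield_consistent_with_cluster_weights(self, default_result):
        p = ModelParameters()
        for s in default_result.days[::13]:
            assert s.y == pytest.approx(sum(s.df) / p.dmc * p.pd / 1000.0, rel=1e-12)

    def test_whole_season_mass_closure(self, default_result):
        """Per plant, cumulative fruit dry weight cannot exceed total dry matter."""
        p = ModelParameters()
        final = default_result.final
        assert sum(final.df) <= final.tdm / p.pd

    def test_ilai_mode_runs_and_tracks_lai_mode(self, default_scenario):
        from strawsim import ScenarioSpec, generate_lai_trajectory

        env, fl, _ = default_scenario
        la = generate_lai_trajectory(ScenarioSpec(), mode="ilai")
        res = simulate_season(env, fl, la)
        assert res.leaf_area_mode == "ilai"
        # the synthetic iLAI is the exact Beer-Lambert image of the LAI path,
        # so the two modes agree closely
        assert res.final.tdm == pytest.approx(472.61, rel=0.01)


class TestMonthlyYield:
    def test_single_month(self):
        env, fl, la = _uniform_inputs(n_days=25, anthesis_dats=(5,))
        res = simulate_season(env, fl, la)
        table = monthly_yield(res)
        assert len(table) == 2  # Sep 18 .. Oct 12 spans two calendar months
        assert table["yield_kg_m2"].sum() == pytest.approx(res.final.y, abs=1e-12)

    def test_increments_telescope_to_final(self, default_result):
        table = monthly_yield(default_result)
        assert table["yield_kg_m2"].sum() == pytest.approx(
            default_result.final.y, rel=1e-12
        )
        assert (table["yield_kg_m2"] >= -1e-15).all()

    def test_pre_flowering_months_zero(self, default_result):
        table = monthly_yield(default_result)
        assert table.iloc[0]["yield_kg_m2"] == 0.0
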