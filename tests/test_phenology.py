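"""Degree-day sums, logistic potential-growth curves, sink strengths."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strawsim import (
    EnvironmentSeries,
    FruitCluster,
    InputError,
    ModelParameters,
    active_leaf_increments,
    cluster_increments,
    cumulative_temperature,
    fruit_relative_growth,
    generative_sink,
    leaf_relative_growth,
    vegetative_sink,
)

D0 = dt.date(2021, 9, 18)
P = ModelParameters()


def make_env(temps):
    dates = [D0 + dt.timedelta(days=i) for i in range(len(temps))]
    return EnvironmentSeries(dates, temps, [1.0] * len(temps))


class TestCumulativeTemperature:
    def test_inclusive_sum(self):
        env = make_env([15.0] * 11)
        assert cumulative_temperature(env, 10) == pytest.approx(165.0)

    def test_day_zero(self):
        assert cumulative_temperature(make_env([18.0]), 0) == 18.0

    def test_arbitrary(self):
        assert cumulative_temperature(make_env([10.0, 20.0, 30.0]), 2) == 60.0

    def test_out_of_range(self):
        with pytest.raises(InputError):
            cumulative_temperature(make_env([15.0] * 3), 3)


class TestLeafRelativeGrowth:
    def test_midpoint(self):
        ct = 160.0 * 2 + 218.86
        assert leaf_relative_growth(ct, 2) == pytest.approx(0.5, abs=1e-12)

    def test_saturation(self):
        assert leaf_relative_growth(1e6, 1) == pytest.approx(1.0, abs=1e-9)

    def test_emergence_tail(self):
        # at the emergence threshold itself (x = 0) the curve sits low
        assert leaf_relative_growth(160.0, 1) == pytest.approx(0.05052759015612883, rel=1e-9)

    def test_bad_index(self):
        with pytest.raises(InputError):
            leaf_relative_growth(100.0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(ct=st.floats(0, 5000), dct=st.floats(0, 500), p=st.integers(1, 20))
    def test_monotone_in_unit_interval(self, ct, dct, p):
        a = leaf_relative_growth(ct, p)
        b = leaf_relative_growth(ct + dct, p)
        assert 0.0 <= a <= b <= 1.0


class TestFruitRelativeGrowth:
    def test_at_anthesis(self):
        assert fruit_relative_growth(0.0) == pytest.approx(1 / 4616.91, rel=1e-9)

    def test_midpoint(self):
        tf = math.log(4615.91) / 0.011
        assert fruit_relative_growth(tf) == pytest.approx(0.5, abs=1e-12)

    def test_saturation(self):
        assert fruit_relative_growth(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            fruit_relative_growth(-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(tf=st.floats(0, 6000), dtf=st.floats(0, 1000))
    def test_monotone_in_unit_interval(self, tf, dtf):
        a = fruit_relative_growth(tf)
        b = fruit_relative_growth(tf + dtf)
        assert 0.0 <= a <= b <= 1.0


class TestActiveLeafIncrements:
    def test_no_accumulation_no_increment(self):
        inc = active_leaf_increments(480.0, 480.0)
        assert inc.shape == (3,)
        assert np.all(inc == 0.0)

    def test_emerged_leaves_only(self):
        # with the 160 degC d emergence interval, 480 degC d means 3 leaves
        inc = active_leaf_increments(480.0, 465.0)
        assert len(inc) == 3
        assert np.all(inc > 0)

    def test_emergence_count_matches_brute_force(self):
        for ct in [0.0, 159.9, 160.0, 321.0, 480.0, 2000.0]:
            inc = active_leaf_increments(ct, max(ct - 10, 0.0))
            brute = sum(1 for p in range(1, 1000) if 160.0 * p <= ct)
            assert len(inc) == brute

    def test_max_leaves_cap(self):
        p = ModelParameters(max_leaves=2)
        assert len(active_leaf_increments(480.0, 465.0, p)) == 2

    def test_telescoping_sum(self):
        """Daily increments of one leaf sum exactly to the endpoint difference."""
        cts = np.arange(160.0, 160.0 + 1500.0 + 15.0, 15.0)
        total = 0.0
        for prev, now in zip(cts, cts[1:]):
            total += active_leaf_increments(now, prev)[0]
        expected = leaf_relative_growth(cts[-1], 1) - leaf_relative_growth(cts[0], 1)
        assert total == pytest.approx(expected, abs=1e-12)


class TestClusterIncrements:
    def make_cluster(self, tf=0.0, rfg_prev=None):
        c = FruitCluster(q=1, anthesis_date=D0)
        c.tf = tf
        c.rfg_prev = rfg_prev
        return c

    def test_no_accumulation_zero(self):
        c = self.make_cluster(tf=100.0, rfg_prev=fruit_relative_growth(100.0))
        assert cluster_increments([c], [100.0])[0] == 0.0

    def test_pre_anthesis_contributes_nothing(self):
        assert cluster_increments([self.make_cluster()], [0.0])[0] == 0.0

    def test_season_total_reaches_cluster_potential(self):
        """Summed daily increments telescope to ~25 g over 0..3000 degC d."""
        c = self.make_cluster()
        total, tf = 0.0, 0.0
        for _ in range(200):
            tf_now = tf + 15.0
            total += cluster_increments([c], [tf_now])[0]
            c.rfg_prev = fruit_relative_growth(tf_now)
            c.tf = tf = tf_now
        closed_form = 25.0 * (fruit_relative_growth(3000.0) - fruit_relative_growth(0.0))
        assert total == pytest.approx(closed_form, abs=1e-12)
        assert total == pytest.approx(24.9946, abs=1e-4)

    def test_midpoint_daily_increment(self):
        """One 15 degC day at the logistic midpoint adds ~25 * rate/4 * 15 g."""
        mid = math.log(4615.91) / 0.011
        c = self.make_cluster(tf=mid - 7.5, rfg_prev=fruit_relative_growth(mid - 7.5))
        inc = cluster_increments([c], [mid + 7.5])[0]
        assert inc == pytest.approx(25.0 * 0.25 * 0.011 * 15.0, rel=0.05)

    def test_step_halving_changes_total_below_1e6(self):
        """Increments are differences of one curve, so refining the step
        leaves the cumulative sum unchanged to floating precision."""
        def run(step):
            tfs = np.arange(step, 3000.0 + step / 2, step)
            prev = np.concatenate([[0.0], tfs[:-1]])
            return float(
                np.sum(25.0 * (fruit_relative_growth(tfs) - fruit_relative_growth(prev)))
            )

        assert abs(run(15.0) - run(7.5)) < 1e-6


class TestSinks:
    def test_generative_examples(self):
        assert generative_sink([]) == 0.0
        assert generative_sink([1.0]) == pytest.approx(0.24)
        assert generative_sink([1.03, 0.40]) == pytest.approx(0.3432, rel=1e-12)

    def test_vegetative_examples(self):
        assert vegetative_sink([]) == 0.0
        assert vegetative_sink([1.0]) == pytest.approx(0.091, rel=1e-12)
        assert vegetative_sink([0.05, 0.04, 0.03]) == pytest.approx(0.01092, rel=1e-12)

    def test_negative_increments_rejected(self):
        with pytest.raises(InputError):
            generative_sink([-0.1])
        with pytest.raises(InputError):
            vegetative_sink([-0.1])
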