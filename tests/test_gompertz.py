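"""Gompertz time-course fitting, inversion and percentile rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from seedgerm.gompertz import (
    GompertzModel,
    aggregate_replicates,
    fit_gompertz,
    gompertz_curve,
    percentile_rates,
    time_to_percentile,
)
from seedgerm.types import (
    Condition,
    GompertzFit,
    NoGerminationError,
    PercentileUnreachableError,
    TimeCourse,
    ValidationError,
)


class TestGompertzCurve:
    @pytest.mark.parametrize(
        "g_max,b,c,t,expected",
        [
            (100.0, 0.05, 0.05, 0.0, 100.0 * np.exp(-1)),  # b=c makes the t=0 exponent -1
            (80.0, 0.3, 0.1, 30.0, 80.0 * np.exp(-3.0 * np.exp(-3.0))),
        ],
    )
    def test_scalar_values(self, g_max, b, c, t, expected):
        assert gompertz_curve(g_max, b, c, t) == pytest.approx(expected, rel=1e-12)

    def test_asymptote_is_g_max(self):
        assert gompertz_curve(90.0, 0.2, 0.05, 1e6) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [dict(g_max=0), dict(g_max=101), dict(b=-1), dict(c=0), dict(t=-1)])
    def test_domain_violations(self, bad):
        kwargs = dict(g_max=90.0, b=0.2, c=0.05, t=10.0)
        kwargs.update(bad)
        with pytest.raises(ValidationError):
            gompertz_curve(kwargs["g_max"], kwargs["b"], kwargs["c"], kwargs["t"])

    @given(
        g_max=st.floats(1.0, 100.0),
        b=st.floats(0.01, 5.0),
        c=st.floats(0.01, 1.0),
        t=st.floats(0.0, 500.0),
        dt=st.floats(0.1, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_non_decreasing_in_time_and_g_max(self, g_max, b, c, t, dt):
        assert gompertz_curve(g_max, b, c, t + dt) >= gompertz_curve(g_max, b, c, t)
        if g_max <= 99.0:
            assert gompertz_curve(g_max + 1.0, b, c, t) >= gompertz_curve(g_max, b, c, t)


class TestInversion:
    def test_t_zero_at_the_t0_value(self):
        fit = GompertzFit(g_max=100.0, b=0.05, c=0.05, rss=0.0, n_obs=10, converged=True)
        assert time_to_percentile(fit, 100.0 * np.exp(-1)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_bisection_oracle(self):
        fit = GompertzFit(g_max=90.0, b=0.2, c=0.05, rss=0.0, n_obs=10, converged=True)
        t_closed = time_to_percentile(fit, 45.0)
        t_bisect = brentq(lambda t: gompertz_curve(90.0, 0.2, 0.05, t) - 45.0, 1e-9, 1e4, xtol=1e-12)
        assert t_closed == pytest.approx(t_bisect, abs=1e-8)

    @given(
        g_max=st.floats(30.0, 100.0),
        b=st.floats(0.05, 2.0),
        c=st.floats(0.01, 0.5),
        frac=st.floats(0.05, 0.95),
    )
    @settings(max_examples=150, deadline=None)
    def test_round_trip_identity(self, g_max, b, c, frac):
        fit = GompertzFit(g_max=g_max, b=b, c=c, rss=0.0, n_obs=10, converged=True)
        g = frac * g_max
        t = time_to_percentile(fit, g)
        if t >= 0:
            assert gompertz_curve(g_max, b, c, t) == pytest.approx(g, abs=1e-9)

    def test_strictly_increasing_in_percentile(self):
        fit = GompertzFit(g_max=95.0, b=0.4, c=0.08, rss=0.0, n_obs=10, converged=True)
        ts = [time_to_percentile(fit, g) for g in (10, 20, 40, 60, 80, 94)]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_unreachable_percentile_raises(self):
        fit = GompertzFit(g_max=37.0, b=0.3, c=0.1, rss=0.0, n_obs=10, converged=True)
        with pytest.raises(PercentileUnreachableError):
            time_to_percentile(fit, 40.0)


class TestAggregateReplicates:
    def _tc(self, times, counts, rep="r1", temp=20.0):
        return TimeCourse(
            species_id="sp", family="f", replicate_id=rep,
            condition=Condition(temp, 0.0), times=times, cumulative_counts=counts,
        )

    def test_single_replicate_identity(self):
        tc = self._tc([10.0, 20.0, 30.0], [5, 10, 20])
        grid, pct = aggregate_replicates([tc])
        np.testing.assert_allclose(grid, tc.times)
        np.testing.assert_allclose(pct, tc.percent)

    def test_mean_of_two_replicates(self):
        a = self._tc([10.0], [5], "r1")
        b = self._tc([10.0], [15], "r2")
        _, pct = aggregate_replicates([a, b])
        assert pct[0] == pytest.approx(40.0)  # (20% + 60%) / 2

    def test_staggered_grids_locf_hand_oracle(self):
        # r1 observed at 10, 30; r2 at 20. Union grid 10, 20, 30.
        # r1 %: 20, 20 (carried), 60 ; r2 %: 0 (before first obs), 40, 40 (carried)
        a = self._tc([10.0, 30.0], [5, 15], "r1")
        b = self._tc([20.0], [10], "r2")
        grid, pct = aggregate_replicates([a, b])
        np.testing.assert_allclose(grid, [10.0, 20.0, 30.0])
        np.testing.assert_allclose(pct, [10.0, 30.0, 50.0])

    def test_mixed_conditions_rejected(self):
        a = self._tc([10.0], [5], "r1", temp=20.0)
        b = self._tc([10.0], [5], "r2", temp=25.0)
        with pytest.raises(ValidationError):
            aggregate_replicates([a, b])


class TestFitGompertz:
    def test_noiseless_parameter_recovery(self):
        t = np.arange(2.0, 200.0, 2.0)
        y = gompertz_curve(95.0, 0.4, 0.08, t)
        fit = fit_gompertz(t, y)
        assert fit.converged
        assert fit.g_max == pytest.approx(95.0, rel=1e-3)
        assert fit.b == pytest.approx(0.4, rel=1e-3)
        assert fit.c == pytest.approx(0.08, rel=1e-3)

    def test_low_plateau_recovery(self):
        t = np.arange(2.0, 300.0, 2.0)
        y = gompertz_curve(37.0, 0.2, 0.05, t)
        fit = fit_gompertz(t, y)
        assert fit.g_max < 40.0

    def test_all_zero_counts_raise(self):
        with pytest.raises(NoGerminationError):
            fit_gompertz([10.0, 20.0, 30.0], [0.0, 0.0, 0.0])

    def test_single_level_curve_flagged_unconverged(self):
        fit = fit_gompertz([10.0, 20.0, 30.0, 40.0], [0.0, 20.0, 20.0, 20.0])
        assert not fit.converged

    def test_rss_no_worse_than_truth_on_noisy_data(self):
        rng = np.random.default_rng(42)
        t = np.arange(2.0, 150.0, 2.0)
        truth = gompertz_curve(80.0, 0.3, 0.07, t)
        y = 100.0 * rng.binomial(100, truth / 100.0) / 100.0
        fit = fit_gompertz(t, y)
        rss_truth = float(np.sum((truth - y) ** 2))
        assert fit.rss <= rss_truth + 1e-9

    def test_g_max_mae_under_binomial_noise(self):
        """25 seeds x 4 replicates: mean absolute Gmax error below 5 points."""
        rng = np.random.default_rng(7)
        t = np.arange(2.0, 120.0, 2.0)
        b, c = 0.35, 0.08
        errs = []
        for _ in range(200):
            counts = np.zeros((4, t.size))
            for rep in range(4):
                k = rng.binomial(25, 0.85)
                u = rng.uniform(size=k)
                times = np.maximum(-np.log(-(c / b) * np.log(u)) / c, 0.0)
                counts[rep] = np.searchsorted(np.sort(times), t, side="right")
            y = 100.0 * counts.mean(axis=0) / 25.0
            errs.append(abs(fit_gompertz(t, y).g_max - 85.0))
        assert float(np.mean(errs)) < 5.0


class TestPercentileRates:
    def test_low_germination_skips_upper_percentiles(self):
        fit = GompertzFit(g_max=37.0, b=0.3, c=0.1, rss=0.0, n_obs=20, converged=True)
        rates, skipped = percentile_rates(fit, (20.0, 30.0, 40.0, 50.0))
        assert [r.percentile_g for r in rates] == [20.0, 30.0]
        assert skipped == [40.0, 50.0]

    def test_full_germination_rates_decrease_with_percentile(self):
        fit = GompertzFit(g_max=100.0, b=0.4, c=0.08, rss=0.0, n_obs=20, converged=True)
        rates, skipped = percentile_rates(fit, (20.0, 30.0, 40.0, 50.0))
        assert not skipped
        vals = [r.rate for r in rates]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        for r in rates:
            assert r.rate == pytest.approx(1.0 / r.time_to_g, rel=1e-12)

    def test_results_skip_percentiles_unreached_by_data(self):
        t = np.arange(2.0, 40.0, 2.0)  # truncated: curve only reaches ~35 %
        y = gompertz_curve(90.0, 2.0, 0.02, t)
        res = GompertzModel(t, y).fit()
        rates, skipped = res.percentile_rates((20.0, 30.0, 40.0, 50.0))
        assert all(g > float(np.max(y)) for g in skipped)
        assert all(r.time_to_g <= t[-1] * 1.0001 for r in rates)
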