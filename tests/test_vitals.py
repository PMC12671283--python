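"""Vital-sign trend regression: OLS correctness, the slope threshold,
latch/reset semantics, and threshold recovery by bisection."""

import numpy as np
import pytest

from ticguard.errors import DegenerateFitError
from ticguard.sensor_model import SensorSample
from ticguard.vitals import (
    SLOPE_THRESHOLD,
    TrendFit,
    VitalBaseline,
    VitalTrendState,
    fit_linear_trend,
    fit_vital_baseline,
    reset_vital,
    trend_flag,
    update_vital,
)

UNIT_BASELINE = VitalBaseline(means={"heart_rate": 0.0}, sds={"heart_rate": 1.0})


def _feed_ramp(state, slope_z_per_min, duration_min, rate_hz=1.0, start_min=0.0):
    """Feed a noiseless linear ramp (z-units) into a vital state."""
    n = int(duration_min * 60 * rate_hz)
    for i in range(n):
        t_s = (start_min * 60.0) + i / rate_hz
        value = slope_z_per_min * (t_s / 60.0)
        update_vital(state, UNIT_BASELINE,
                     SensorSample(t_s, "heart_rate", (value,)), now=t_s)
    return state


class TestLinearTrend:
    def test_two_point_line(self):
        fit = fit_linear_trend([(0.0, 1.0), (1.0, 3.0)])
        assert fit.b0 == pytest.approx(1.0)
        assert fit.b1 == pytest.approx(2.0)

    def test_constant_series_flat(self):
        fit = fit_linear_trend([(t, 5.0) for t in range(10)])
        assert fit.b1 == pytest.approx(0.0, abs=1e-12)

    def test_against_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        t = np.sort(rng.uniform(0, 60, 100))
        y = 1.7 - 0.4 * t + rng.normal(0, 2, 100)
        X = np.column_stack([np.ones(100), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # closed-form OLS
        fit = fit_linear_trend(np.column_stack([t, y]))
        assert fit.b0 == pytest.approx(beta[0], abs=1e-10)
        assert fit.b1 == pytest.approx(beta[1], abs=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(22)
        t = np.arange(50, dtype=float)
        y = 2 + 0.5 * t + rng.normal(0, 1, 50)
        fit = fit_linear_trend(np.column_stack([t, y]))
        resid = y - (fit.b0 + fit.b1 * t)
        assert abs(np.dot(resid, t - t.mean())) < 1e-9 * np.abs(y).sum() * t.max()

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_linear_trend([(1.0, 2.0)])
        with pytest.raises(DegenerateFitError):
            fit_linear_trend([(1.0, 2.0), (1.0, 3.0)])


class TestTrendFlag:
    @pytest.mark.parametrize("slope,expected", [
        (1.5, True),
        (4.0 / 3.0, True),       # boundary is inclusive
        (-4.0 / 3.0, True),
        (0.0, False),
        (1.3, False),
        (-5.0, True),
    ])
    def test_threshold(self, slope, expected):
        fit = TrendFit(b0=0.0, b1=slope, n=10, span_minutes=5.0)
        assert trend_flag(fit) is expected


class TestLatch:
    def test_steep_ramp_latches(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        assert state.latched and state.p_vital == 1

    def test_flat_series_never_latches(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 0.0, 10.0)
        assert not state.latched and state.p_vital == 0

    def test_latched_state_ignores_new_trends(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        assert state.latched
        # steeply falling data afterwards must not change P_Vital
        for i in range(120):
            t = 360.0 + i
            update_vital(state, UNIT_BASELINE,
                         SensorSample(t, "heart_rate", (12.0 - t / 10.0,)), now=t)
        assert state.p_vital == 1

    def test_channel_mismatch_rejected(self):
        state = VitalTrendState("heart_rate")
        with pytest.raises(ValueError):
            update_vital(state, UNIT_BASELINE,
                         SensorSample(0.0, "temperature", (36.6,)), now=0.0)

    def test_noiseless_slope_recovered_exactly(self):
        state = VitalTrendState("heart_rate", threshold=np.inf)
        _feed_ramp(state, 0.9, 10.0)
        assert state.last_fit.b1 == pytest.approx(0.9, abs=1e-9)

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(30)
        s = 1.0  # z/min
        t_min = np.arange(60) / 6.0  # 10 min at 0.1 Hz
        z = s * t_min + rng.normal(0, 0.1, 60)
        fit = fit_linear_trend(np.column_stack([t_min, z]))
        assert abs(fit.b1 - s) < 0.05


class TestReset:
    def test_reset_on_flat_buffer_clears(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        assert state.latched
        # buffer refills with flat values while latched
        for i in range(600):
            t = 360.0 + i
            update_vital(state, UNIT_BASELINE,
                         SensorSample(t, "heart_rate", (0.0,)), now=t)
        reset_vital(state, "confirm", now=960.0)
        assert not state.latched and state.p_vital == 0

    def test_reset_relatches_if_trend_persists(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        assert state.latched
        reset_vital(state, "confirm", now=360.0)
        assert state.latched  # ramp still fills the trend window

    def test_double_confirm_is_noop_with_warning(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        for i in range(600):  # flat refill so the first reset clears
            t = 360.0 + i
            update_vital(state, UNIT_BASELINE,
                         SensorSample(t, "heart_rate", (0.0,)), now=t)
        reset_vital(state, "confirm", now=960.0)
        assert not state.latched
        with pytest.warns(UserWarning, match="no-op"):
            reset_vital(state, "confirm", now=961.0)
        assert not state.latched

    def test_confirm_on_unlatched_warns(self):
        state = VitalTrendState("heart_rate")
        with pytest.warns(UserWarning, match="no-op"):
            reset_vital(state, "confirm", now=0.0)


class TestBisection:
    def test_minimal_latched_slope_equals_threshold(self):
        """Bisection on noiseless ramps recovers the 4/3 z/min threshold."""

        def latches(slope):
            state = VitalTrendState("heart_rate")
            _feed_ramp(state, slope, 8.0)
            return state.latched

        lo, hi = 0.0, 3.0
        assert not latches(lo) and latches(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if latches(mid):
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(SLOPE_THRESHOLD, abs=1e-6)
        assert SLOPE_THRESHOLD == pytest.approx(4.0 / 3.0)

    def test_latch_monotone_while_latched(self):
        state = VitalTrendState("heart_rate")
        _feed_ramp(state, 2.0, 6.0)
        rng = np.random.default_rng(33)
        for i in range(200):
            t = 360.0 + i
            update_vital(state, UNIT_BASELINE,
                         SensorSample(t, "heart_rate", (rng.normal(0, 5),)), now=t)
            assert state.p_vital == 1


class TestBaseline:
    def test_fit_from_stream(self, twin_sim):
        stream, _, _ = twin_sim
        baseline = fit_vital_baseline(stream)
        for ch in ("heart_rate", "temperature", "humidity"):
            assert baseline.sds[ch] > 0
        # simulator baseline heart rate is 75 +/- 3 bpm
        assert baseline.means["heart_rate"] == pytest.approx(75.0, abs=2.0)

    def test_zero_variance_warns(self):
        from ticguard.sensor_model import SensorStream

        s = SensorStream(
            times={"heart_rate": np.arange(5.0)},
            values={"heart_rate": np.full((5, 1), 70.0)},
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            baseline = fit_vital_baseline(s)
        assert baseline.sds["heart_rate"] == 1.0
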