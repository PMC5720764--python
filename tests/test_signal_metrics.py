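import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pivload.exceptions import InvalidInputError
from pivload.loads import LoadSeries
from pivload.signal_metrics import (
    ComparisonReport,
    TransverseSample,
    adjusted_cutoff,
    compare_traces,
    correlation_with_ci,
    lowpass_dual_pass,
    phase_average,
    phase_lag,
    resolve_forces,
    rmse_percent,
    subtract_rod,
    vz_star,
)


class TestResolveForces:
    def test_identity_at_zero(self):
        assert resolve_forces(1.2, -0.7, 0.0) == (1.2, -0.7)

    def test_quarter_turn(self):
        Fx, Fy = resolve_forces(0.0, 1.0, np.pi / 2)
        assert np.isclose(Fx, 1.0) and np.isclose(Fy, 0.0, atol=1e-12)

    def test_thirty_degrees(self):
        Fx, Fy = resolve_forces(1.0, 0.0, np.pi / 6)
        assert np.isclose(Fx, 0.86603, atol=1e-5)
        assert np.isclose(Fy, -0.5, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-10, 10), st.floats(-10, 10), st.floats(-2 * np.pi, 2 * np.pi)
    )
    def test_magnitude_preserved(self, fx, fy, theta):
        Fx, Fy = resolve_forces(fx, fy, theta)
        assert np.isclose(np.hypot(Fx, Fy), np.hypot(fx, fy), atol=1e-9)


class TestAdjustedCutoff:
    def test_single_pass_unchanged(self):
        assert adjusted_cutoff(7.0, 2, 1) == pytest.approx(7.0)

    def test_two_pass_order_two_value(self):
        assert round(adjusted_cutoff(7.0, 2, 2), 2) == 8.73

    def test_ten_hz(self):
        assert round(adjusted_cutoff(10.0, 2, 2), 2) == 12.47

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            adjusted_cutoff(0.0, 2, 2)


class TestLowpassDualPass:
    def test_constant_unchanged(self):
        x = np.full(500, 3.3)
        assert np.allclose(lowpass_dual_pass(x, 1000.0, 7.0), x, atol=1e-9)

    def test_passband_amplitude_and_zero_phase(self):
        t = np.arange(0, 5, 0.001)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_dual_pass(x, 1000.0, 7.0)
        assert abs(np.max(y[1000:4000]) - 1.0) < 0.01
        # zero net phase: peak cross-correlation at zero samples
        lag = phase_lag(x, y, period=1.0, fs=1000.0)
        assert abs(lag) <= 0.1  # <= 1 sample of 1000

    def test_stopband_attenuation(self):
        t = np.arange(0, 5, 0.001)
        x = np.sin(2 * np.pi * 50.0 * t)
        y = lowpass_dual_pass(x, 1000.0, 7.0)
        assert np.abs(y[1000:4000]).max() < 0.1

    def test_output_length(self):
        x = np.random.default_rng(0).normal(size=777)
        assert lowpass_dual_pass(x, 1000.0, 7.0).shape == x.shape

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidInputError):
            lowpass_dual_pass(np.zeros(100), 10.0, 7.0)


class TestSubtractRod:
    def _series(self, fx, provenance):
        n = len(fx)
        return LoadSeries.from_arrays(
            np.arange(n) * 0.01, fx, np.zeros(n), np.zeros(n), provenance=provenance
        )

    def test_zero_rod_unchanged(self):
        a = self._series([1.0, 2.0, 3.0], "measured")
        r = self._series([0.0, 0.0, 0.0], "rod")
        out = subtract_rod(a, r)
        assert np.allclose(out.Fx, [1, 2, 3])
        assert out.provenance == "foil-only"

    def test_identical_series_zero(self):
        a = self._series([1.0, 2.0, 3.0], "measured")
        out = subtract_rod(a, self._series([1.0, 2.0, 3.0], "rod"))
        assert np.allclose(out.Fx, 0.0)

    def test_elementwise_difference(self):
        a = self._series([1.0, 2.0], "measured")
        r = self._series([0.5, 0.5], "rod")
        assert np.allclose(subtract_rod(a, r).Fx, [0.5, 1.5])

    def test_non_overlapping_rejected(self):
        a = LoadSeries.from_arrays([10.0, 10.01], [1, 1], [0, 0], [0, 0])
        r = self._series([0.0, 0.0], "rod")
        with pytest.raises(InvalidInputError):
            subtract_rod(a, r)


class TestPhaseAverage:
    def test_identical_cycles(self):
        cycle = np.array([0.0, 1.0, 0.0, -1.0])
        mean, sd = phase_average(np.tile(cycle, 3), period=1.0, n_cycles=3, fs=4.0)
        assert np.allclose(mean, cycle) and np.allclose(sd, 0.0)

    def test_two_cycle_sd(self):
        mean, sd = phase_average(np.array([1.0, 1.0, 3.0, 3.0]), 1.0, 2, fs=2.0)
        assert np.allclose(mean, [2.0, 2.0])
        assert np.allclose(sd, np.sqrt(2.0))

    def test_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            phase_average(np.ones(5), period=1.0, n_cycles=3, fs=2.0)

    def test_unresolvable_period_rejected(self):
        with pytest.raises(InvalidInputError):
            phase_average(np.ones(10), period=0.1, n_cycles=2, fs=1.0)


class TestCorrelationWithCI:
    def test_perfect_correlation(self):
        x = np.sin(np.linspace(0, 10, 100))
        r, _ = correlation_with_ci(x, x)
        assert np.isclose(r, 1.0)

    def test_orthogonal_sin_cos(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r, _ = correlation_with_ci(np.sin(t), np.cos(t))
        assert abs(r) < 1e-10

    def test_fisher_ci_formula(self):
        # independent closed form at r = 0.9, n = 200:
        # tanh(atanh(0.9) -/+ 1.96/sqrt(197)) = (0.86988, 0.92343)
        z = np.arctanh(0.9)
        h = 1.96 / np.sqrt(197)
        lo, hi = np.tanh(z - h), np.tanh(z + h)
        assert np.isclose(lo, 0.869877, atol=1e-6)
        assert np.isclose(hi, 0.923435, atol=1e-6)
        # the implementation reproduces the same interval on data with that r
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=200)
            y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=200)
            r, (clo, chi) = correlation_with_ci(x, y)
            zz = np.arctanh(r)
            assert np.isclose(clo, np.tanh(zz - h), atol=1e-12)
            assert np.isclose(chi, np.tanh(zz + h), atol=1e-12)

    def test_matches_scipy_ci(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        y = 0.7 * x + rng.normal(size=150)
        res = stats.pearsonr(x, y)
        ci = res.confidence_interval()
        r, (lo, hi) = correlation_with_ci(x, y)
        assert np.isclose(r, res.statistic, atol=1e-12)
        assert np.isclose(lo, ci.low, atol=1e-5)
        assert np.isclose(hi, ci.high, atol=1e-5)

    def test_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            correlation_with_ci(np.ones(10), np.arange(10.0))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r0, _ = correlation_with_ci(x, y)
        r1, _ = correlation_with_ci(x, scale * y + offset)
        assert np.isclose(r0, r1, atol=1e-9)


class TestRmsePercent:
    def test_identical_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rmse_percent(x, x) == 0.0

    def test_printed_toy_vectors(self):
        assert np.isclose(rmse_percent(np.array([2.0, 2, 2]), np.array([1.0, 2, 3])), 40.82, atol=0.005)
        assert np.isclose(rmse_percent(np.array([2.0, 3, 4]), np.array([1.0, 2, 3])), 50.0, atol=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            rmse_percent(np.array([1.0, 2.0]), np.array([1.0, 1.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.01, 100.0))
    def test_joint_scaling_invariance(self, k):
        M = np.array([2.0, 2.5, 2.0, 1.5])
        C = np.array([1.0, 2.0, 3.0, 2.0])
        assert np.isclose(rmse_percent(k * M, k * C), rmse_percent(M, C), rtol=1e-9)


class TestPhaseLag:
    FS = 100.0
    PERIOD = 1.0

    def _sine(self, n_cycles=3):
        t = np.arange(0, n_cycles * self.PERIOD, 1 / self.FS)
        return np.sin(2 * np.pi * t / self.PERIOD)

    def test_zero_for_identical(self):
        M = self._sine()
        assert phase_lag(M, M, self.PERIOD, self.FS) == 0.0

    def test_quarter_period_delay(self):
        M = self._sine()
        C = np.roll(M, 25)  # delayed by period/4
        assert abs(phase_lag(M, C, self.PERIOD, self.FS) - 25.0) <= 1.0

    def test_tenth_period_advance(self):
        M = self._sine()
        C = np.roll(M, -10)
        assert abs(phase_lag(M, C, self.PERIOD, self.FS) - (-10.0)) <= 1.0

    def test_recovery_up_to_half_period(self):
        # circular shifts of a periodic signal are ambiguous modulo one
        # period, so assess recovery by modular distance
        M = self._sine(n_cycles=4)
        for shift in (-50, -20, 0, 20, 49):
            C = np.roll(M, shift)
            got = phase_lag(M, C, self.PERIOD, self.FS)
            err = min(abs(got - shift - 100 * k) for k in (-1, 0, 1))
            assert err <= 1.0  # within one sample (1% here)

    def test_flat_input_rejected(self):
        with pytest.raises(InvalidInputError):
            phase_lag(np.ones(200), np.ones(200), self.PERIOD, self.FS)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            phase_lag(np.sin(np.arange(10.0)), np.sin(np.arange(10.0)), 30.0, 0.5)


class TestVzStar:
    def test_in_plane(self):
        assert vz_star(0.3, -0.2, 0.0) == 0.0

    def test_pure_vertical(self):
        assert vz_star(0.0, 0.0, -0.4) == 1.0

    def test_345_triangle(self):
        assert np.isclose(vz_star(4.0, 0.0, 3.0), 0.6, rtol=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            vz_star(0.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
    )
    def test_bounded_unit_interval(self, vx, vy, vz):
        if vx == vy == vz == 0.0:
            return
        assert 0.0 <= vz_star(vx, vy, vz) <= 1.0

    def test_sample_constructor(self):
        s = TransverseSample.from_velocities(4.0, 0.0, 3.0)
        assert s.Vz_star == 0.6


class TestCompareTraces:
    def test_report_fields(self):
        t = np.arange(0, 3, 0.01)
        M = np.sin(2 * np.pi * t)
        C = 0.95 * np.sin(2 * np.pi * t) + 0.01
        rep = compare_traces(M, C, period=1.0, fs=100.0)
        assert rep.r > 0.999
        assert rep.ci95[0] <= rep.r <= rep.ci95[1]
        assert rep.rmse_pct < 5.0
        assert rep.lag_pct == 0.0
        d = rep.to_dict()
        assert "conventions" in d and d["n"] == t.size

    def test_ci_must_bracket_r(self):
        with pytest.raises(InvalidInputError):
            ComparisonReport(r=0.9, ci95=(0.95, 0.99), rmse_pct=1.0, lag_pct=0.0, n=10)
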