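import numpy as np
import pytest

import optomap as om
from optomap.errors import (
    DurationNotReachedError,
    NoTransientError,
    TauNotReachedError,
    ValidationError,
)


def trace_of(values, fps=1000.0):
    return om.Trace(values=np.asarray(values, dtype=float), fps=fps)


class TestSmoothedDerivatives:
    def test_linear_ramp(self):
        m = 0.25  # per ms
        tr = trace_of(m * np.arange(100))
        d1, d2 = om.smoothed_derivatives(tr, 5)
        np.testing.assert_allclose(d1.values[5:-5], m, rtol=1e-9)
        np.testing.assert_allclose(d2.values[5:-5], 0.0, atol=1e-9)

    def test_quadratic_curvature(self):
        a = 0.01
        t = np.arange(200, dtype=float)
        tr = trace_of(a * t**2)
        _d1, d2 = om.smoothed_derivatives(tr, 5)
        np.testing.assert_allclose(d2.values[10:-10], 2 * a, rtol=1e-6)

    def test_sine_matches_analytic_cosine(self):
        f = 5.0  # Hz
        t = np.arange(2000) / 1000.0  # s
        tr = trace_of(np.sin(2 * np.pi * f * t))
        d1, _ = om.smoothed_derivatives(tr, 1)
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t) / 1000.0  # per ms
        core = slice(10, -10)
        rms = np.sqrt(np.mean((d1.values[core] - expected[core]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(expected[core] ** 2))

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            om.smoothed_derivatives(trace_of(np.zeros(50)), 4)

    def test_window_too_long_rejected(self):
        with pytest.raises(ValidationError):
            om.smoothed_derivatives(trace_of(np.zeros(10)), 9)


class TestDetectFeatures:
    def test_piecewise_linear_transient(self, full_window):
        """Rise over frames 10-14, then linear decay: max slope at the rise
        midpoint, peak at frame 14."""
        v = np.zeros(80)
        v[10:15] = np.linspace(0.0, 1.0, 5)
        v[15:] = np.maximum(1.0 - (np.arange(65) + 1) / 45.0, 0.0)
        tr = trace_of(v)
        f = om.detect_features(tr, full_window(tr), smooth_window=3)
        assert abs(f.activation_time - 12.0) <= 1.0
        assert f.peak_time == pytest.approx(14.0)
        assert f.peak_value == pytest.approx(1.0)

    def test_flat_trace_raises_no_transient(self, full_window):
        tr = trace_of(np.zeros(100))
        with pytest.raises(NoTransientError):
            om.detect_features(tr, full_window(tr))

    def test_landmark_ordering_invariant(self, full_window):
        for seed in range(20):
            spec = om.PhantomSpec(noise_sd=0.16, seed=seed, emit_inverted=False)
            tr, _ = om.make_trace(spec)
            tr = om.temporal_filter(tr, 100.0)
            f = om.detect_features(tr, full_window(tr))
            assert (
                f.start_time
                <= f.activation_time
                < f.peak_time
                <= f.downstroke_time
                <= f.end_time
            )

    def test_phantom_activation_recovery_under_noise(self, full_window):
        """Activation lands within one frame of the generator truth, SNR 50."""
        errs = []
        for seed in range(30):
            spec = om.PhantomSpec(noise_sd=0.16, seed=seed)  # SNR 50
            tr, truth = om.make_trace(spec)
            tr = om.temporal_filter(om.invert_polarity(tr), 100.0)
            f = om.detect_features(tr, full_window(tr))
            errs.append(abs(f.activation_time - truth.activation_time_ms))
        assert np.mean(errs) <= 1.0
        assert np.max(errs) <= 2.0

    def test_inversion_round_trip_gives_identical_features(
        self, voltage_trace_clean, full_window
    ):
        trace, _ = voltage_trace_clean
        w = full_window(trace)
        f1 = om.detect_features(trace, w)
        f2 = om.detect_features(
            om.invert_polarity(om.invert_polarity(trace)), w
        )
        assert f1 == f2


class TestDuration:
    def test_linear_decay_analytic_crossing(self, full_window):
        """Instant rise to 1, linear fall to 0 over 100 ms: the 80% level
        (0.2) is crossed 80 ms into the decay."""
        v = np.zeros(150)
        v[10] = 0.5  # single-frame rise support for the derivative
        v[11:111] = np.linspace(1.0, 0.0, 100, endpoint=False)
        v[111:] = 0.0
        tr = trace_of(v)
        w = full_window(tr, percent=80.0)
        f = om.detect_features(tr, w, smooth_window=1)
        d = om.duration(tr, f, w)
        t_cross_expected = 11.0 + 80.0  # decay start + 80% of 100 ms
        assert d == pytest.approx(t_cross_expected - f.activation_time, abs=1.0)

    @pytest.mark.parametrize("p_lo,p_hi", [(30.0, 50.0), (50.0, 80.0), (80.0, 95.0)])
    def test_monotone_in_percent(self, voltage_trace_clean, full_window, p_lo, p_hi):
        trace, _ = voltage_trace_clean
        w_lo = full_window(trace, percent=p_lo)
        w_hi = full_window(trace, percent=p_hi)
        f = om.detect_features(trace, w_lo)
        assert om.duration(trace, f, w_lo) <= om.duration(trace, f, w_hi)

    def test_phantom_apd80_recovery(self, voltage_trace_clean, full_window):
        trace, truth = voltage_trace_clean
        w = full_window(trace)
        f = om.detect_features(trace, w)
        assert om.duration(trace, f, w) == pytest.approx(
            truth.apd80_ms, abs=trace.dt_ms
        )

    def test_duration_not_reached(self, full_window):
        v = np.zeros(100)
        v[20:30] = np.linspace(0.0, 1.0, 10)
        v[30:] = np.linspace(1.0, 0.6, 70)  # never recovers to the 20% level
        tr = trace_of(v)
        w = full_window(tr)
        f = om.detect_features(tr, w, smooth_window=3)
        with pytest.raises(DurationNotReachedError):
            om.duration(tr, f, w)

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValidationError):
            om.AnalysisWindow(0.0, 100.0, percent=0.0)
        with pytest.raises(ValidationError):
            om.AnalysisWindow(0.0, 100.0, percent=100.0)


class TestDiastolicInterval:
    def _feat(self, act):
        return om.TransientFeatures(
            start_time=act - 20, f0=0.0, onset_time=act - 5,
            activation_time=act, peak_time=act + 10, peak_value=1.0,
            downstroke_time=act + 30, end_time=act + 60,
        )

    def test_arithmetic(self):
        di = om.diastolic_interval(self._feat(0.0), 60.0, self._feat(160.0))
        assert di == pytest.approx(100.0)

    def test_overlapping_transients_rejected(self):
        with pytest.raises(ValidationError):
            om.diastolic_interval(self._feat(0.0), 60.0, self._feat(50.0))

    def test_periodic_pacing_identity(self):
        """Multi-beat phantom: DI + duration = cycle length within a frame."""
        cl = 200.0
        spec = om.PhantomSpec(n_beats=4, cycle_length_ms=cl, emit_inverted=False)
        tr, _ = om.make_trace(spec)
        beats = om.analyze_beats(tr, percent=80.0)
        assert len(beats) == 4
        for (f_k, d_k), (f_n, _) in zip(beats, beats[1:]):
            di = om.diastolic_interval(f_k, d_k, f_n)
            assert di + d_k == pytest.approx(cl, abs=tr.dt_ms)


class TestDecayTau:
    def test_exact_exponential(self, full_window):
        tau = 50.0
        t = np.arange(400, dtype=float)
        v = np.zeros(400)
        v[40:50] = np.linspace(0, 1, 10)
        v[50:] = np.exp(-(t[50:] - 50.0) / tau)
        tr = trace_of(v)
        f = om.detect_features(tr, full_window(tr), smooth_window=3)
        assert om.decay_tau(tr, f) == pytest.approx(tau, abs=1.5)

    def test_linear_decay_crossing(self, full_window):
        T = 100.0
        v = np.zeros(160)
        v[10] = 0.5
        v[11:111] = np.linspace(1.0, 0.0, 100, endpoint=False)
        tr = trace_of(v)
        f = om.detect_features(tr, full_window(tr), smooth_window=1)
        assert om.decay_tau(tr, f) == pytest.approx((1 - 1 / np.e) * T, abs=1.5)

    def test_truncated_trace_raises(self, full_window):
        v = np.zeros(60)
        v[40:50] = np.linspace(0, 1, 10)
        v[50:] = 1.0  # never decays
        tr = trace_of(v)
        f = om.detect_features(tr, full_window(tr), smooth_window=3)
        with pytest.raises(TauNotReachedError):
            om.decay_tau(tr, f)


class TestAmplitudeDff0:
    def test_simple_ratio(self, full_window):
        v = np.full(120, 100.0)
        v[50:60] = np.linspace(100.0, 110.0, 10)
        v[60:] = np.linspace(110.0, 100.0, 60)
        tr = trace_of(v)
        f = om.detect_features(tr, full_window(tr), smooth_window=3)
        assert om.amplitude_dff0(tr, f) == pytest.approx(0.10, abs=0.005)

    def test_scale_invariance(self, voltage_trace_clean, full_window):
        trace, _ = voltage_trace_clean
        w = full_window(trace)
        f = om.detect_features(trace, w)
        a1 = om.amplitude_dff0(trace, f)
        scaled = om.Trace(values=3.7 * trace.values, fps=trace.fps)
        f2 = om.detect_features(scaled, w)
        assert om.amplitude_dff0(scaled, f2) == pytest.approx(a1, rel=1e-9)

    def test_phantom_fractional_amplitude(self, full_window):
        """Generator sets amplitude/F0 = 8/100; recovered within 5% at SNR 100."""
        vals = []
        for seed in range(20):
            spec = om.PhantomSpec(noise_sd=0.08, seed=seed, emit_inverted=False)
            tr, _ = om.make_trace(spec)
            cond = om.temporal_filter(tr, 100.0)
            f = om.detect_features(cond, full_window(cond))
            vals.append(om.amplitude_dff0(tr, f))
        assert np.mean(vals) == pytest.approx(0.08, rel=0.05)

    def test_nonpositive_f0_rejected(self, voltage_trace_clean, full_window):
        trace, _ = voltage_trace_clean
        w = full_window(trace)
        f = om.detect_features(trace, w)
        detrended = om.detrend(trace, 0)  # baseline now ~0
        with pytest.raises(ValidationError):
            om.amplitude_dff0(detrended, f)
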