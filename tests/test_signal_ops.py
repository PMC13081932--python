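"""Filtering, envelope, exponential-fit and baseline primitives."""

import numpy as np
import pytest

from voltscope.signal_ops import (
    correct_photobleach_biexp,
    dff_highpass,
    dff_polynomial,
    dff_rolling_percentile,
    ewma_smooth,
    fit_exponential,
    hilbert_analytic,
    slow_bleach_powerlaw_slope,
    zero_phase_filter,
)
from voltscope.timeseries import TimeSeries


class TestZeroPhaseFilter:
    def test_highpass_rejects_dc(self):
        ts = TimeSeries(np.full(10000, 7.3), 1000.0)
        out = zero_phase_filter(ts, "butterworth", "highpass", 2, 0.5)
        assert np.abs(out.values).max() < 1e-6 * 7.3

    def test_bandpass_preserves_in_band_tone(self):
        rate = 1000.0
        t = np.arange(0, 20, 1 / rate)
        ts = TimeSeries(np.sin(2 * np.pi * 5 * t), rate)
        out = zero_phase_filter(ts, "butterworth", "bandpass", 2, (2.0, 10.0))
        mid = slice(2000, -2000)
        amp = np.abs(out.values[mid]).max()
        assert abs(amp - 1.0) < 0.01
        # zero phase: cross-correlation peak at zero lag
        xc = np.correlate(out.values[mid], ts.values[mid], "full")
        lag = np.argmax(xc) - (len(xc) // 2)
        assert lag == 0

    def test_lowpass_attenuation_matches_squared_transfer_function(self):
        rate, f, fc, order = 2000.0, 100.0, 12.0, 3
        t = np.arange(0, 10, 1 / rate)
        ts = TimeSeries(np.sin(2 * np.pi * f * t), rate)
        out = zero_phase_filter(ts, "butterworth", "lowpass", order, fc)
        measured = np.abs(out.values[2000:-2000]).max()
        expected = 1.0 / (1.0 + (f / fc) ** (2 * order))  # |H|^2, forward+backward
        assert measured == pytest.approx(expected, rel=0.05)

    def test_time_reversal_commutes(self):
        rng = np.random.default_rng(0)
        ts = TimeSeries(rng.standard_normal(5000), 500.0)
        fwd = zero_phase_filter(ts, "bessel", "bandpass", 3, (5.0, 50.0)).values
        rev = zero_phase_filter(ts.copy(values=ts.values[::-1]), "bessel",
                                "bandpass", 3, (5.0, 50.0)).values
        # identical away from the padded edges (IIR startup transients decay)
        np.testing.assert_allclose(fwd[200:-200], rev[::-1][200:-200], atol=1e-4)

    def test_nan_gap_interpolated_and_remasked(self):
        t = np.arange(0, 10, 1e-3)
        vals = np.sin(2 * np.pi * 2 * t)
        vals[5000:5050] = np.nan
        out = zero_phase_filter(TimeSeries(vals, 1000.0), "butterworth", "lowpass", 2, 10.0)
        assert np.isnan(out.values[5000:5050]).all()
        assert not np.isnan(np.delete(out.values, slice(5000, 5050))).any()

    def test_cutoff_validation(self):
        ts = TimeSeries(np.zeros(100), 100.0)
        with pytest.raises(ValueError):
            zero_phase_filter(ts, "butterworth", "lowpass", 2, 60.0)  # >= Nyquist
        with pytest.raises(ValueError):
            zero_phase_filter(TimeSeries(np.full(100, np.nan), 100.0),
                              "butterworth", "lowpass", 2, 10.0)


class TestHilbert:
    def test_sine_envelope_and_phase(self):
        rate = 1000.0
        t = np.arange(0, 10, 1 / rate)
        ts = TimeSeries(3.0 * np.sin(2 * np.pi * 4 * t), rate)
        env, phase = hilbert_analytic(ts)
        mid = slice(1000, -1000)
        assert np.abs(env.values[mid] / 3.0 - 1).max() < 0.01
        # cosine-referenced convention: phase 0 at the signal maxima
        peaks = np.flatnonzero((ts.values[1:-1] > ts.values[:-2])
                               & (ts.values[1:-1] > ts.values[2:])) + 1
        peaks = peaks[(peaks > 1000) & (peaks < len(t) - 1000)]
        assert np.abs(phase.values[peaks]).max() < 0.05

    def test_chirp_amplitude_ramp_recovered(self):
        rate = 1000.0
        t = np.arange(0, 10, 1 / rate)
        amp = 1.0 + 0.5 * t
        x = amp * np.sin(2 * np.pi * (5 * t + 0.5 * t ** 2))
        env, _ = hilbert_analytic(TimeSeries(x, rate))
        mid = slice(1000, 9000)
        rel = np.abs(env.values[mid] / amp[mid] - 1)
        assert rel.max() < 0.05

    def test_nan_rejected(self):
        vals = np.ones(100)
        vals[3] = np.nan
        with pytest.raises(ValueError):
            hilbert_analytic(TimeSeries(vals, 100.0))


class TestFitExponential:
    def test_exact_single_recovery(self):
        rate = 10000.0
        t = np.arange(0, 1.5, 1 / rate)
        y = np.where(t > 0.5, 2 + 3 * np.exp(-(t - 0.5) / 0.01), 5.0)
        fit = fit_exponential(TimeSeries(y, rate), "single")
        assert fit.c == pytest.approx(2.0, abs=1e-6)
        assert fit.k == pytest.approx(3.0, abs=1e-6)
        assert fit.tau_s == pytest.approx(0.010, abs=1e-6)
        assert fit.t0 == pytest.approx(0.5, abs=1e-6)

    def test_dual_recovery_at_physiological_taus(self):
        # tau 0.5 / 7.5 ms with 85/15 weights at SNR 50
        rng = np.random.default_rng(3)
        rate = 50000.0
        t = np.arange(0, 0.1, 1 / rate)
        clean = np.where(t > 0.02,
                         1 + 0.85 * np.exp(-(t - 0.02) / 5e-4)
                         + 0.15 * np.exp(-(t - 0.02) / 7.5e-3), 2.0)
        y = clean + (1 / 50) * rng.standard_normal(t.size)
        fit = fit_exponential(TimeSeries(y, rate), "dual")
        assert fit.tau_s == pytest.approx(5e-4, rel=0.10)
        assert fit.tau2_s == pytest.approx(7.5e-3, rel=0.10)
        assert fit.fast_fraction == pytest.approx(0.85, abs=0.05)

    def test_constant_input_degenerate(self):
        fit = fit_exponential(TimeSeries(np.full(1000, 4.2), 1000.0), "single")
        assert fit.degenerate
        assert fit.c == pytest.approx(4.2)
        assert fit.k == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 0.5, 1e-4)
        y = np.where(t > 0.1, 1 + np.exp(-(t - 0.1) / 0.02), 2.0) \
            + 0.01 * rng.standard_normal(t.size)
        a = fit_exponential(TimeSeries(y, 10000.0), "single")
        b = fit_exponential(TimeSeries(y, 10000.0), "single")
        assert (a.c, a.k, a.lam, a.t0) == (b.c, b.k, b.lam, b.t0)


class TestPhotobleach:
    @staticmethod
    def _biexp_trace(rate=100.0, dur=120.0, mod=None):
        t = np.arange(0, dur, 1 / rate)
        bleach = 0.3 * np.exp(-t / 5) + 0.7 * np.exp(-t / 500)
        vals = 100 * bleach
        if mod is not None:
            vals = vals * (1 + mod(t))
        return TimeSeries(vals, rate)

    def test_pure_biexponential_divides_to_one(self):
        corr, _ = correct_photobleach_biexp(self._biexp_trace())
        assert np.abs(corr.values / 100 - 1).max() < 1e-4

    def test_recovers_multiplicative_sinusoid(self):
        corr, _ = correct_photobleach_biexp(
            self._biexp_trace(mod=lambda t: 0.05 * np.sin(2 * np.pi * 5 * t)))
        rec = corr.values / 100 - 1
        assert rec.std() * np.sqrt(2) == pytest.approx(0.05, rel=0.02)

    def test_flat_input_unchanged(self):
        ts = TimeSeries(np.full(2000, 50.0), 100.0)
        corr, fit = correct_photobleach_biexp(ts)
        assert fit.degenerate
        np.testing.assert_array_equal(corr.values, ts.values)

    def test_idempotent_within_half_percent(self):
        corr1, _ = correct_photobleach_biexp(self._biexp_trace())
        corr2, _ = correct_photobleach_biexp(corr1)
        rel = np.abs(corr2.values - corr1.values) / np.abs(corr1.values).mean()
        assert rel.max() < 0.005


class TestPowerlawSlope:
    @pytest.mark.parametrize("exponent,tol", [(-0.1, 0.005), (0.0, 1e-3)])
    def test_exact_power_law(self, exponent, tol):
        rate = 1000.0
        t = np.arange(1, 600, 1 / rate)
        ts = TimeSeries(t ** exponent, rate, t0_s=1.0)
        assert slow_bleach_powerlaw_slope(ts) == pytest.approx(exponent, abs=tol)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(0)
        rate = 1000.0
        t = np.arange(1, 600, 1 / rate)
        ts = TimeSeries(t ** -0.2 + 0.01 * rng.standard_normal(t.size), rate, t0_s=1.0)
        assert slow_bleach_powerlaw_slope(ts) == pytest.approx(-0.2, abs=0.02)

    def test_nonpositive_values_rejected(self):
        ts = TimeSeries(np.linspace(1, -1, 200000), 1000.0, t0_s=1.0)
        with pytest.raises(ValueError):
            slow_bleach_powerlaw_slope(ts)


class TestDffConventions:
    def test_highpass_constant_gives_zero(self):
        out = dff_highpass(TimeSeries(np.full(5000, 10.0), 500.0))
        assert np.abs(out.values).max() < 1e-9

    def test_highpass_fast_wiggle_scales_to_percent(self):
        rate = 500.0
        t = np.arange(0, 20, 1 / rate)
        out = dff_highpass(TimeSeries(10 + np.sin(2 * np.pi * 5 * t), rate))
        assert np.abs(out.values[2000:-2000]).max() == pytest.approx(10.0, rel=0.02)

    def test_highpass_removes_slow_drift(self):
        rate = 500.0
        t = np.arange(0, 60, 1 / rate)
        out = dff_highpass(TimeSeries(10 + np.sin(2 * np.pi * 0.05 * t), rate))
        # residual drift well below the original +-10% swing
        assert np.ptp(out.values[3000:-3000]) < 0.05 * 20.0

    def test_highpass_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            dff_highpass(TimeSeries(np.full(1000, -1.0), 100.0))

    def test_polynomial_exact_cubic_baseline(self):
        x = np.arange(2000, dtype=float)
        f = 100 + 0.01 * x - 1e-5 * x ** 2 + 1e-9 * x ** 3
        neg, f0 = dff_polynomial(TimeSeries(f, 100.0))
        assert np.abs(neg.values).max() < 1e-9
        assert neg.values.min() == 0.0

    def test_polynomial_negative_transient(self):
        x = np.arange(2000, dtype=float)
        f = 100 + 0.01 * x - 1e-5 * x ** 2
        f[1000:1010] *= 0.9
        neg, _ = dff_polynomial(TimeSeries(f, 100.0))
        assert neg.values[1000:1010].max() == pytest.approx(0.10, abs=1e-3)
        assert np.abs(neg.values[:900]).max() < 5e-3
        assert neg.values.min() == 0.0

    def test_polynomial_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            dff_polynomial(TimeSeries(np.ones(100), 10.0), exclude_mask=np.ones(100, bool))

    def test_rolling_percentile_constant_is_zero(self):
        out = dff_rolling_percentile(TimeSeries(np.full(2000, 5.0), 20.0))
        assert np.abs(out.values).max() < 1e-12

    def test_rolling_percentile_dip_arithmetic(self):
        rate = 20.0
        y = np.full(int(30 * 60 * rate), 10.0)
        for i in np.arange(0, y.size, 1000):
            y[i:i + 70] = 9.0     # dips carry ~7% of each window
        out = dff_rolling_percentile(TimeSeries(y, rate), invert=False)
        assert np.median(out.values) == pytest.approx((10 - 9) / 9, abs=0.005)

    def test_rolling_percentile_window_longer_than_trace(self):
        y = np.full(1200, 10.0)
        y[:60] = 9.0   # 5% of the trace
        out = dff_rolling_percentile(TimeSeries(y, 1.0), window_min=60.0, invert=False)
        assert np.isfinite(out.values).all()


class TestEwma:
    def test_constant_unchanged(self):
        out = ewma_smooth(TimeSeries(np.full(500, 3.0), 100.0), 20.0)
        np.testing.assert_allclose(out.values, 3.0)

    def test_step_reaches_63_percent_at_tau(self):
        step = np.concatenate([np.zeros(100), np.ones(400)])
        out = ewma_smooth(TimeSeries(step, 1000.0), decay_ms=50.0)
        i63 = np.argmax(out.values >= 1 - np.exp(-1))
        assert abs((i63 - 100) - 50) <= 1
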