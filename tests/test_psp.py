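"""PSP quality control, deconvolution, detection windows, and metrics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from optomap import psp

from conftest import DT_MS, make_epoch, double_exp


class TestQcSweeps:
    def test_flat_trace_accepted(self):
        assert len(psp.qc_sweeps([make_epoch()])) == 1

    def test_offset_baseline_rejected(self):
        epoch = make_epoch(holding=-70.0)
        epoch.voltage += 6.0  # 6 mV off the -70 mV target: > 5 mV rule
        assert psp.qc_sweeps([epoch], holding_target=-70.0) == []

    def test_ramp_in_pre_window_rejected(self):
        def ramp(t):
            out = np.zeros_like(t)
            pre = (t >= -50) & (t < 0)
            out[pre] = 1.5 * (t[pre] + 50) / 50.0  # 1.5 mV over 50 ms: > 1 mV rule
            out[t >= 0] = 1.5
            return out

        assert psp.qc_sweeps([make_epoch(fn=ramp)]) == []

    def test_all_rejected_returns_empty(self):
        epochs = [make_epoch(holding=-70.0) for _ in range(3)]
        for e in epochs:
            e.voltage += 10.0
        assert psp.qc_sweeps(epochs, holding_target=-70.0) == []


class TestBaselineSubtract:
    def test_constant_trace_becomes_zero(self):
        out = psp.baseline_subtract(make_epoch(holding=-70.0))
        assert np.allclose(out.voltage, 0.0)

    def test_dc_shift_invariance(self):
        base = make_epoch(fn=lambda t: double_exp(t, 0.5, 5.0))
        shifted = make_epoch(fn=lambda t: double_exp(t, 0.5, 5.0))
        shifted.voltage = shifted.voltage + 3.0
        np.testing.assert_allclose(
            psp.baseline_subtract(base).voltage,
            psp.baseline_subtract(shifted).voltage,
            atol=1e-12,
        )

    def test_post_hoc_median_is_zero(self, rng):
        epoch = make_epoch(fn=lambda t: rng.normal(0, 0.3, t.size))
        out = psp.baseline_subtract(epoch)
        window = out.voltage[out.window_slice(-20.0, 0.0)]
        assert np.median(window) == pytest.approx(0.0, abs=1e-12)


class TestDeconvolve:
    def test_constant_maps_to_itself(self):
        d = psp.deconvolve(np.full(100, 3.3), tau=20.0, dt_ms=0.1)
        np.testing.assert_allclose(d, 3.3)

    def test_matched_exponential_cancels(self):
        t = np.arange(0, 100, 0.1)
        v = 2.0 * np.exp(-t / 20.0)
        d = psp.deconvolve(v, tau=20.0, dt_ms=0.1)
        # away from the onset edge the matched exponential deconvolves to ~0
        assert np.max(np.abs(d[2:])) < 1e-3

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            psp.deconvolve(np.zeros(10), tau=0.0, dt_ms=0.1)

    def test_linearity(self, rng):
        v1, v2 = rng.normal(size=(2, 500))
        a, b = 2.5, -1.3
        left = psp.deconvolve(a * v1 + b * v2, 20.0, 0.1)
        right = a * psp.deconvolve(v1, 20.0, 0.1) + b * psp.deconvolve(v2, 20.0, 0.1)
        np.testing.assert_allclose(left, right, atol=1e-10)

    def test_double_exp_peak_matches_analytic_derivative(self):
        """Deconvolved peak time agrees with the closed-form D(t) maximum."""
        rise, decay, tau, amp, onset = 1.5, 18.0, 20.0, 1.0, 5.0
        epoch = make_epoch(fn=lambda t: double_exp(t, amp, onset, rise, decay))
        epoch = psp.baseline_subtract(epoch)
        dec = psp.deconvolve_epoch(epoch, tau)

        t_peak_k = rise * decay / (decay - rise) * np.log(decay / rise)
        norm = np.exp(-t_peak_k / decay) - np.exp(-t_peak_k / rise)

        def d_analytic(t):
            e_d, e_r = np.exp(-t / decay), np.exp(-t / rise)
            return ((e_d - e_r) + tau * (-e_d / decay + e_r / rise)) * amp / norm

        # numerically maximize the analytic D on a fine grid (independent oracle)
        tt = np.linspace(1e-6, 50.0, 200001)
        t_star = tt[np.argmax(d_analytic(tt))] + onset
        i_star = np.argmax(dec[epoch.stim_onset_index :])
        assert i_star * DT_MS == pytest.approx(t_star, abs=DT_MS + 1e-9)


class TestDetectWindow:
    def test_noise_only_rarely_detects(self, rng):
        """5×SD threshold keeps the false-positive rate at or below ~1%."""
        hits = 0
        n = 100
        for _ in range(n):
            epoch = make_epoch(fn=lambda t: rng.normal(0, 0.05, t.size))
            epoch = psp.baseline_subtract(epoch)
            if psp.detect_psp_window(epoch):
                hits += 1
        assert hits <= 1  # >= 99% of fixtures yield no window

    def test_single_psp_window_near_true_onset(self):
        epoch = make_epoch(fn=lambda t: double_exp(t, 1.0, 5.0))
        epoch = psp.baseline_subtract(epoch)
        windows = psp.detect_psp_window(epoch)
        assert len(windows) == 1
        assert windows[0][0] == pytest.approx(5.0, abs=1.0)

    def test_two_psps_split_at_interpeak_minimum(self):
        fn = lambda t: double_exp(t, 1.0, 5.0, 1.0, 8.0) + double_exp(
            t, 1.0, 13.0, 1.0, 8.0
        )
        epoch = psp.baseline_subtract(make_epoch(fn=fn))
        windows = psp.detect_psp_window(epoch)
        assert len(windows) == 2
        w1, w2 = windows
        assert w1[1] <= w2[0] + 1e-9  # separated at the inter-peak minimum
        assert w1[0] == pytest.approx(5.0, abs=1.0)
        assert w2[0] == pytest.approx(13.0, abs=2.0)


class TestAmplitudeCv:
    def test_identical_sweeps_cv_zero(self):
        epochs = [
            psp.baseline_subtract(make_epoch(fn=lambda t: double_exp(t, 0.5, 5.0)))
            for _ in range(5)
        ]
        amp, cv = psp.measure_amplitude_cv(epochs, (5.0, 25.0))
        assert amp == pytest.approx(0.5, abs=1e-3)  # one-sample discretization
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_amplitude_recovery(self):
        epochs = [
            psp.baseline_subtract(make_epoch(fn=lambda t: double_exp(t, 0.3, 5.0)))
        ]
        amp, _ = psp.measure_amplitude_cv(epochs, (5.0, 25.0))
        assert amp == pytest.approx(0.3, abs=1e-3)


class TestRiseTime:
    def test_linear_ramp_gives_60_percent_of_duration(self):
        def ramp(t):
            out = np.zeros_like(t)
            rising = (t >= 0) & (t <= 10)
            out[rising] = t[rising] / 10.0
            out[t > 10] = 1.0
            return out

        epoch = psp.baseline_subtract(make_epoch(fn=ramp))
        assert psp.rise_time(epoch, (0.0, 12.0)) == pytest.approx(6.0, abs=0.05)

    def test_double_exp_matches_root_finding_oracle(self):
        rise, decay, amp = 1.5, 18.0, 1.0
        epoch = psp.baseline_subtract(
            make_epoch(fn=lambda t: double_exp(t, amp, 0.0, rise, decay))
        )
        t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
        norm = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)

        def kernel(t):
            return (np.exp(-t / decay) - np.exp(-t / rise)) / norm

        t20 = brentq(lambda t: kernel(t) - 0.2, 1e-9, t_peak)
        t80 = brentq(lambda t: kernel(t) - 0.8, 1e-9, t_peak)
        measured = psp.rise_time(epoch, (0.0, 20.0))
        assert measured == pytest.approx(t80 - t20, abs=DT_MS + 1e-9)

    def test_small_amplitude_undefined(self):
        epoch = psp.baseline_subtract(
            make_epoch(fn=lambda t: double_exp(t, 0.05, 5.0))
        )
        assert np.isnan(psp.rise_time(epoch, (5.0, 25.0)))


class TestPairedPulseRatio:
    def test_identical_nonoverlapping_psps(self):
        fn = lambda t: double_exp(t, 1.0, 5.0, 1.0, 5.0) + double_exp(
            t, 1.0, 60.0, 1.0, 5.0
        )
        epochs = [psp.baseline_subtract(make_epoch(fn=fn)) for _ in range(3)]
        train = psp.paired_pulse_ratio(epochs, (0.0, 40.0), (55.0, 90.0), tau=5.0)
        assert train.ppr == pytest.approx(1.0, abs=0.01)

    def test_summation_corrected_ppr(self):
        """Second PSP at half amplitude riding on the first's decay."""
        rise, decay = 1.0, 10.0
        fn = lambda t: double_exp(t, 1.0, 5.0, rise, decay) + double_exp(
            t, 0.5, 12.0, rise, decay
        )
        epochs = [psp.baseline_subtract(make_epoch(fn=fn)) for _ in range(3)]
        avg = psp.average_epoch(epochs)
        sl2 = avg.window_slice(11.0, 25.0)
        raw_ratio = np.max(avg.voltage[sl2])  # raw second peak rides on the first
        assert raw_ratio > 0.55  # temporal summation inflates the raw ratio
        train = psp.paired_pulse_ratio(
            epochs, (3.0, 11.0), (11.0, 30.0), tau=decay
        )
        assert train.ppr == pytest.approx(0.5, abs=0.02)
        assert train.inter_psp_interval == pytest.approx(7.0, abs=1.0)

    def test_interval_filter_for_population(self):
        fn = lambda t: double_exp(t, 1.0, 5.0, 1.0, 5.0) + double_exp(
            t, 1.0, 17.0, 1.0, 5.0
        )
        epochs = [psp.baseline_subtract(make_epoch(fn=fn))]
        train = psp.paired_pulse_ratio(epochs, (3.0, 12.0), (14.0, 30.0), tau=5.0)
        assert train.inter_psp_interval == pytest.approx(12.0, abs=1.0)
        assert not train.in_population_interval  # outside the 5-10 ms filter

    def test_tau_grid_selection_runs(self):
        fn = lambda t: double_exp(t, 1.0, 5.0, 0.8, 8.0) + double_exp(
            t, 0.8, 12.0, 0.8, 8.0
        )
        epochs = [psp.baseline_subtract(make_epoch(fn=fn))]
        train = psp.paired_pulse_ratio(epochs, (3.0, 11.0), (11.0, 30.0))
        assert train.tau_used in psp.PPR_TAU_GRID_MS


class TestRundown:
    def test_constant_amplitudes(self):
        assert psp.rundown([0.5] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_decline(self):
        amps = 1.0 - 0.01 * np.arange(20)  # 1% of the initial amplitude per sweep
        slope = psp.rundown(amps)
        # slope normalized to the mean amplitude, so slightly steeper than -1%
        assert slope == pytest.approx(-0.01 / np.mean(amps) * 100, rel=1e-9)

    def test_noisy_slope_within_2_se(self, rng):
        true_slope = -0.005
        n = 50
        amps = 1.0 + true_slope * np.arange(n) + rng.normal(0, 0.02, n)
        from scipy.stats import linregress

        fit = linregress(np.arange(n), amps)
        measured = psp.rundown(amps)
        expected = 100 * fit.slope / np.mean(amps)
        assert measured == pytest.approx(expected, rel=1e-9)
        assert abs(fit.slope - true_slope) < 2 * fit.stderr

    def test_too_few_sweeps_error(self):
        with pytest.raises(ValueError):
            psp.rundown([1.0, 1.0])
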