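"""Spectral pipeline: filter, scalogram, QC, Welch, spike statistics."""

import numpy as np
import pytest

from mecgamma.analysis import (QCCriteria, Scalogram, bandpass_filter,
                               cycle_average_scalogram, find_gamma_peak,
                               histogram_autocorr_frequency,
                               isi_frequency_histogram, morlet_cwt,
                               population_spike_histogram,
                               spike_phase_histogram, total_gamma_power,
                               welch_psd)

FS = 10000.0
SCALE_STEP = 2.0 ** (1.0 / 32.0)


def theta_gamma_trace(gamma=100.0, amp=100.0, cycles=41, fs=FS, theta=8.0):
    t = np.arange(int(cycles * fs / theta)) / fs
    env = 0.5 * (1 - np.cos(2 * np.pi * theta * t))
    return amp * env * np.sin(2 * np.pi * gamma * t)


class TestBandpass:
    def test_dc_rejection(self):
        out = bandpass_filter(np.full(20000, 123.0), FS)
        assert np.max(np.abs(out)) < 1e-9 * 123.0

    def test_passband_preserved(self):
        t = np.arange(50000) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        out = bandpass_filter(x, FS)
        mid = slice(10000, 40000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        t = np.arange(50000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        out = bandpass_filter(x, FS)
        assert np.abs(out[10000:40000]).max() < 10 ** (-20 / 20)

    def test_zero_phase(self):
        """Cross-correlation of a filtered narrowband signal peaks at 0."""
        rng = np.random.default_rng(0)
        t = np.arange(40000) / FS
        x = np.sin(2 * np.pi * 120.0 * t) + 0.1 * rng.standard_normal(t.size)
        y = bandpass_filter(x, FS)
        seg = slice(5000, 35000)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[seg], np.roll(y, k)[seg]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), 300.0)


class TestScalogram:
    def test_pure_carrier_frequency_recovered(self):
        x = theta_gamma_trace(gamma=100.0)
        scal = cycle_average_scalogram(x, FS)
        pk = find_gamma_peak(scal)
        assert pk.frequency == pytest.approx(100.0, rel=SCALE_STEP - 1)

    def test_frequency_grid_geometric(self):
        f, _, _ = morlet_cwt(np.zeros(4096), FS)
        ratios = f[1:] / f[:-1]
        np.testing.assert_allclose(ratios, SCALE_STEP, rtol=1e-12)

    def test_sinusoid_amplitude_convention(self):
        """|W| ~ A for a pure sinusoid at its own frequency."""
        t = np.arange(40000) / FS
        x = 57.0 * np.sin(2 * np.pi * 100.0 * t)
        f, c, _ = morlet_cwt(x, FS)
        i = np.argmin(np.abs(f - 100.0))
        assert np.abs(c[i, 15000:25000]).mean() == pytest.approx(57.0,
                                                                 rel=0.02)

    def test_zero_trace_zero_power(self):
        scal = cycle_average_scalogram(np.zeros(int(FS * 0.5)), FS)
        assert np.all(scal.power == 0)

    def test_artifact_cycle_excluded_without_bias(self):
        clean = theta_gamma_trace()
        dirty = clean.copy()
        dirty[int(5.3 * FS / 8.0)] += 5000.0  # contaminate cycle 5
        s_clean = cycle_average_scalogram(clean, FS)
        s_dirty = cycle_average_scalogram(dirty, FS)
        assert (5, "artifact") in s_dirty.excluded_cycles
        assert s_dirty.n_cycles == s_clean.n_cycles - 1
        ratio = s_dirty.power.max() / s_clean.power.max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_first_cycle_always_dropped(self):
        scal = cycle_average_scalogram(theta_gamma_trace(cycles=41), FS)
        assert (0, "first-cycle") in scal.excluded_cycles
        assert scal.n_cycles == 40

    def test_all_cycles_excluded_raises(self):
        x = np.full(int(2 * FS / 8.0), 4000.0)
        with pytest.raises(ValueError, match="all cycles excluded"):
            cycle_average_scalogram(x, FS)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            cycle_average_scalogram(np.zeros(100), FS)


class TestGammaPeakQC:
    def test_strong_peak_passes(self):
        x = theta_gamma_trace(gamma=120.0, amp=100.0)
        pk = find_gamma_peak(cycle_average_scalogram(x, FS))
        assert pk.passed_qc and not pk.qc_reasons
        assert pk.frequency == pytest.approx(120.0, rel=SCALE_STEP - 1)

    def test_white_noise_fails_snr(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 50.0, int(41 * FS / 8.0))
        pk = find_gamma_peak(cycle_average_scalogram(x, FS))
        assert not pk.passed_qc
        assert "low-snr" in pk.qc_reasons

    def test_low_power_reason(self):
        x = theta_gamma_trace(gamma=100.0, amp=2.0)  # peak power ~4 pA^2
        pk = find_gamma_peak(cycle_average_scalogram(x, FS))
        assert "low-power" in pk.qc_reasons

    def test_threshold_boundary_inclusive(self):
        """A peak power of exactly 20 pA^2 passes (removal is strict <)."""
        freqs = 60.0 * 2.0 ** (np.arange(40) / 32.0)
        power = np.full((40, 100), 1e-3)
        power[20, 50] = 20.0
        scal = Scalogram(frequencies=freqs,
                         phase=np.linspace(0, 2 * np.pi, 100, False),
                         power=power, coi_mask=np.ones_like(power, bool),
                         n_cycles=40)
        pk = find_gamma_peak(scal, QCCriteria.thy1())
        assert pk.passed_qc

    def test_amplitude_scaling_quadratic_and_snr_invariant(self):
        x = theta_gamma_trace(gamma=100.0, amp=50.0)
        p1 = find_gamma_peak(cycle_average_scalogram(x, FS))
        p2 = find_gamma_peak(cycle_average_scalogram(3.0 * x, FS))
        assert p2.power == pytest.approx(9.0 * p1.power, rel=1e-6)
        assert p2.frequency == p1.frequency
        assert p2.snr == pytest.approx(p1.snr, rel=1e-6)


class TestTotalGammaPower:
    def test_zero_trace(self):
        scal = cycle_average_scalogram(np.zeros(int(FS)), FS)
        assert total_gamma_power(scal) == 0.0

    def test_separated_bands_additive(self):
        a = theta_gamma_trace(gamma=80.0, amp=60.0)
        b = theta_gamma_trace(gamma=120.0, amp=60.0)
        pa = total_gamma_power(cycle_average_scalogram(a, FS))
        pb = total_gamma_power(cycle_average_scalogram(b, FS))
        pab = total_gamma_power(cycle_average_scalogram(a + b, FS))
        assert pab == pytest.approx(pa + pb, rel=0.10)

    def test_out_of_band_excluded(self):
        hi = theta_gamma_trace(gamma=170.0, amp=100.0)
        inb = theta_gamma_trace(gamma=100.0, amp=100.0)
        p_hi = total_gamma_power(cycle_average_scalogram(hi, FS))
        p_in = total_gamma_power(cycle_average_scalogram(inb, FS))
        assert p_hi < 0.05 * p_in


class TestWelch:
    def test_peak_location(self):
        t = np.arange(int(5 * FS)) / FS
        f, p = welch_psd(np.sin(2 * np.pi * 100.0 * t), FS)
        assert f[np.argmax(p)] == pytest.approx(100.0, abs=f[1] - f[0])

    def test_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(5 * FS))
        f, p = welch_psd(x, FS)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(x.var(), rel=0.05)

    def test_white_noise_flat_in_gamma_band(self):
        rng = np.random.default_rng(4)
        f, p = welch_psd(rng.standard_normal(int(5 * FS)), FS)
        band = p[(f >= 60) & (f <= 140)]
        assert band.max() / band.min() < 3.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(50), FS)


class TestSpikePhaseHistogram:
    def test_empty(self):
        hist, excl = spike_phase_histogram([], 8.0, 40)
        assert np.all(hist == 0) and excl == 0

    def test_single_bin_for_crest_locked_spikes(self):
        spikes = 62.5 + 125.0 * np.arange(40)  # crest of each cycle
        hist, excl = spike_phase_histogram(spikes, 8.0, 40)
        assert excl == 0
        assert hist.sum() == pytest.approx(1.0)
        assert hist.max() == pytest.approx(1.0)

    def test_normalization_and_exclusion(self):
        spikes = [10.0, 5100.0]  # second spike outside the 40-cycle window
        hist, excl = spike_phase_histogram(spikes, 8.0, 40)
        assert excl == 1
        assert hist.sum() == pytest.approx(1.0 / 40.0)

    def test_uniform_spikes_flat_within_multinomial_bands(self):
        rng = np.random.default_rng(6)
        n = 10000
        spikes = rng.uniform(0, 40 * 125.0, n)
        hist, _ = spike_phase_histogram(spikes, 8.0, 40)
        counts = hist * 40
        p = 1 / 30
        sd = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3.3 * sd)


class TestISIHistogram:
    def test_regular_train(self):
        spikes = np.arange(0, 1000, 10.0)  # 100 Hz
        edges, hist = isi_frequency_histogram(spikes, 40)
        occupied = np.nonzero(hist)[0]
        assert len(occupied) == 1
        assert edges[occupied[0]] == 100.0

    def test_single_spike_empty(self):
        _, hist = isi_frequency_histogram([5.0], 40)
        assert hist.sum() == 0

    def test_mixture_proportions(self):
        """7 and 14 ms ISIs land at ~143 and ~71 Hz in the right ratio."""
        isis = np.array([7.0] * 300 + [14.0] * 100)
        rng = np.random.default_rng(7)
        rng.shuffle(isis)
        spikes = np.concatenate([[0.0], np.cumsum(isis)])
        edges, hist = isi_frequency_histogram(spikes, 40)
        bin_143 = int(1000 / 7.0 // 10)
        bin_71 = int(1000 / 14.0 // 10)
        assert hist[bin_143] * 40 == 300
        assert hist[bin_71] * 40 == 100


class TestAutocorrFrequency:
    def test_periodic_histogram(self):
        t = np.arange(2000)
        hist = (t % 7 == 0).astype(float)
        f = histogram_autocorr_frequency(hist, 1.0)
        assert f == pytest.approx(1000.0 / 7.0, rel=0.02)

    def test_flat_histogram_absent(self):
        assert histogram_autocorr_frequency(np.ones(1000), 1.0) is None
        assert histogram_autocorr_frequency(np.zeros(1000), 1.0) is None

    def test_modulated_poisson_population(self):
        """100 Hz-modulated Poisson spikes across 400 cells -> 100 Hz."""
        rng = np.random.default_rng(8)
        dt, dur = 0.1, 5000.0
        t = np.arange(0, dur, dt)
        rate = 50.0 / 1000.0 * (1 + 0.8 * np.sin(2 * np.pi * 0.1 * t))
        counts = rng.poisson(rate * dt * 400)
        hist = counts.reshape(-1, 10).sum(axis=1)  # 1 ms bins
        f = histogram_autocorr_frequency(hist, 1.0)
        assert f == pytest.approx(100.0, rel=0.07)


def test_population_histogram_counts_all_spikes():
    trains = [np.array([10.0, 20.0]), np.array([15.0])]
    centers, hist = population_spike_histogram(trains, 1.0, 0.0, 30.0)
    assert hist.sum() == 3


def test_morlet_agrees_with_pywavelets_reference():
    """Independent cross-check: peak frequency from our analytic-Morlet
    transform matches PyWavelets' complex Morlet CWT on the same trace."""
    import pywt

    t = np.arange(20000) / FS
    x = np.sin(2 * np.pi * 110.0 * t) + 0.4 * np.sin(2 * np.pi * 70.0 * t)
    f_own, c_own, _ = morlet_cwt(x, FS)
    i_own = np.argmax(np.abs(c_own[:, 5000:15000]).mean(axis=1))

    fc = 6.0 / (2 * np.pi)  # omega0 = 6 as a cycles-per-sample frequency
    wavelet = pywt.ContinuousWavelet(f"cmor2.0-{fc}")
    scales = fc * FS / f_own
    coef, freqs = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / FS)
    i_ref = np.argmax(np.abs(coef[:, 5000:15000]).mean(axis=1))
    # pywt derives its center frequency from the discretized waveform, so
    # its frequency mapping differs by a small discretization bias
    assert abs(freqs[i_ref] - f_own[i_own]) / f_own[i_own] < 0.05
    assert f_own[i_own] == pytest.approx(110.0, rel=0.025)
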