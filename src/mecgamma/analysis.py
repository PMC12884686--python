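"""Spectral and spike-train analysis of theta-nested gamma activity.

The core quantity is the cycle-averaged Morlet scalogram of a current
trace: the continuous wavelet transform with the analytic Morlet wavelet
(omega0 = 6 rad/s, 32 scales per octave) is computed over the whole
recording, segmented into theta cycles, and the power surfaces of the
accepted cycles (first cycle and artifact cycles excluded) are averaged.
Peak frequency/power/phase, full-width-at-half-maximum bandwidth and SNR
(peak power over whole-surface mean power) are then read off the average
surface, with quality-control thresholds matching intracellular gamma
recordings (minimum peak power, maximum bandwidth, SNR >= 5, 3,000 pA
artifact rejection).

Wavelet convention: the transform is L1-normalized (frequency-domain
window ``2 exp(-(s w - w0)^2 / 2)`` on positive frequencies only), so a
pure sinusoid of amplitude A yields |W| ~ A at its frequency and "power"
|W|^2 ~ A^2 in pA^2.  Scale maps to frequency as f = w0 / (2 pi s).
The cone of influence marks samples farther than the e-folding time
sqrt(2)*s of the wavelet envelope from both recording edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "QCCriteria",
    "Scalogram",
    "GammaPeak",
    "bandpass_filter",
    "morlet_cwt",
    "cycle_average_scalogram",
    "find_gamma_peak",
    "total_gamma_power",
    "welch_psd",
    "spike_phase_histogram",
    "isi_frequency_histogram",
    "population_spike_histogram",
    "histogram_autocorr_frequency",
    "analyze_trace",
]

OMEGA0 = 6.0  # rad/s, analytic Morlet center frequency
SCALES_PER_OCTAVE = 32
FREQ_RANGE = (30.0, 250.0)  # Hz analyzed band (context around 60-140)


@dataclass(frozen=True)
class QCCriteria:
    """Exclusion thresholds for gamma-peak quality control.

    Thresholds are inclusive for passing (a peak power exactly at
    ``min_peak_power`` passes), since removals are defined by strict
    inequalities.
    """

    min_peak_power: float = 20.0  # pA^2
    max_bandwidth: float = 100.0  # Hz
    min_snr: float = 5.0
    artifact_threshold: float = 3000.0  # pA
    gamma_band: tuple = (60.0, 140.0)  # Hz, for total power

    def __post_init__(self) -> None:
        for name in ("min_peak_power", "max_bandwidth", "min_snr",
                     "artifact_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def thy1(cls) -> "QCCriteria":
        return cls(min_peak_power=20.0, max_bandwidth=100.0)

    @classmethod
    def pv(cls) -> "QCCriteria":
        return cls(min_peak_power=10.0, max_bandwidth=110.0)


@dataclass
class Scalogram:
    """Cycle-averaged time-frequency power surface.

    ``power[i, j]`` is the mean squared wavelet magnitude (pA^2) at
    ``frequencies[i]`` and within-cycle phase ``phase[j]``; ``coi_mask``
    is True where every averaged cycle is free of recording-edge effects.
    """

    frequencies: np.ndarray  # Hz, ascending, ratio 2**(1/32)
    phase: np.ndarray  # radians in [0, 2 pi)
    power: np.ndarray  # (n_freq, n_phase) pA^2
    coi_mask: np.ndarray  # bool, same shape
    n_cycles: int
    excluded_cycles: list = field(default_factory=list)  # (index, reason)


@dataclass
class GammaPeak:
    """Located scalogram maximum plus quality-control outcome."""

    frequency: float  # Hz
    power: float  # pA^2
    theta_phase: float  # radians
    bandwidth: float  # Hz (FWHM along frequency at the peak phase)
    snr: float  # peak power / mean surface power
    passed_qc: bool
    qc_reasons: list = field(default_factory=list)


def bandpass_filter(trace, fs: float, low: float = 50.0,
                    high: float = 200.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-reverse) Butterworth band-pass."""
    if fs <= 2.0 * high:
        raise ValueError("sampling rate must exceed twice the upper edge")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def _freq_grid(fmin: float, fmax: float) -> np.ndarray:
    n = int(np.floor(np.log2(fmax / fmin) * SCALES_PER_OCTAVE)) + 1
    return fmax * 2.0 ** (-np.arange(n)[::-1] / SCALES_PER_OCTAVE)


def morlet_cwt(trace, fs: float, freqs=None):
    """Analytic Morlet CWT, L1-normalized, via FFT.

    Returns (freqs ascending, coefficients (n_freq, n_samples) complex,
    coi_time seconds per frequency: samples closer than this to either
    recording edge are edge-contaminated).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if freqs is None:
        freqs = _freq_grid(*FREQ_RANGE)
    freqs = np.asarray(freqs, dtype=float)
    scales = OMEGA0 / (2.0 * np.pi * freqs)  # seconds
    xf = np.fft.fft(x)
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)  # rad/s
    pos = w > 0
    coefs = np.empty((freqs.size, n), dtype=complex)
    for i, s in enumerate(scales):
        window = np.zeros(n)
        window[pos] = 2.0 * np.exp(-0.5 * (s * w[pos] - OMEGA0) ** 2)
        coefs[i] = np.fft.ifft(xf * window)
    coi_time = np.sqrt(2.0) * scales
    return freqs, coefs, coi_time


def _cycle_slices(n_samples: int, fs: float, theta_freq: float):
    samp = int(round(fs / theta_freq))
    n_cyc = n_samples // samp
    return samp, n_cyc


def detect_artifact_cycles(trace, fs: float, theta_freq: float,
                           threshold: float) -> list:
    """Indices of theta cycles containing any |sample| > threshold."""
    trace = np.asarray(trace)
    samp, n_cyc = _cycle_slices(trace.size, fs, theta_freq)
    return [c for c in range(n_cyc)
            if np.any(np.abs(trace[c * samp:(c + 1) * samp]) > threshold)]


def cycle_average_scalogram(trace, fs: float, theta_freq: float = 8.0,
                            criteria: QCCriteria = QCCriteria(),
                            exclude_first: bool = True,
                            prefilter: bool = False) -> Scalogram:
    """Average the per-cycle Morlet power surfaces of ``trace``.

    Artifact detection uses the raw trace; the optional 50-200 Hz
    zero-phase band-pass is applied before the wavelet transform.  The
    transform runs on the continuous trace and is segmented afterwards, so
    cycle boundaries interior to the recording carry no edge artifacts;
    the cone of influence applies at the recording edges only.
    """
    raw = np.asarray(trace, dtype=float)
    samp, n_cyc = _cycle_slices(raw.size, fs, theta_freq)
    if n_cyc < 2:
        raise ValueError("trace must span at least two theta cycles")
    excluded = []
    if exclude_first:
        excluded.append((0, "first-cycle"))
    for c in detect_artifact_cycles(raw, fs, theta_freq,
                                    criteria.artifact_threshold):
        if not any(c == e[0] for e in excluded):
            excluded.append((c, "artifact"))
    keep = [c for c in range(n_cyc) if not any(c == e[0] for e in excluded)]
    if not keep:
        raise ValueError(f"all cycles excluded: {excluded}")

    x = bandpass_filter(raw, fs) if prefilter else raw
    freqs, coefs, coi_time = morlet_cwt(x[:n_cyc * samp], fs)
    power = np.abs(coefs) ** 2
    n = n_cyc * samp
    t_edge = np.minimum(np.arange(n), n - 1 - np.arange(n)) / fs
    valid = t_edge[None, :] >= coi_time[:, None]  # (n_freq, n)

    acc = np.zeros((freqs.size, samp))
    mask = np.ones((freqs.size, samp), dtype=bool)
    for c in keep:
        sl = slice(c * samp, (c + 1) * samp)
        acc += power[:, sl]
        mask &= valid[:, sl]
    acc /= len(keep)
    phase = 2.0 * np.pi * np.arange(samp) / samp
    return Scalogram(frequencies=freqs, phase=phase, power=acc,
                     coi_mask=mask, n_cycles=len(keep),
                     excluded_cycles=excluded)


def find_gamma_peak(scal: Scalogram,
                    criteria: QCCriteria = QCCriteria()) -> GammaPeak:
    """Global maximum of the averaged surface, with QC reason codes."""
    p = scal.power
    i, j = np.unravel_index(np.argmax(p), p.shape)
    peak_power = float(p[i, j])
    freq = float(scal.frequencies[i])
    mean_power = float(p.mean())
    snr = peak_power / mean_power if mean_power > 0 else 0.0

    # FWHM along frequency at the peak's theta phase
    profile = p[:, j]
    half = peak_power / 2.0
    above = profile >= half
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < profile.size - 1 and above[hi + 1]:
        hi += 1
    bandwidth = float(scal.frequencies[hi] - scal.frequencies[lo])

    reasons = []
    if peak_power < criteria.min_peak_power:
        reasons.append("low-power")
    if bandwidth > criteria.max_bandwidth:
        reasons.append("broadband")
    if snr < criteria.min_snr:
        reasons.append("low-snr")
    return GammaPeak(frequency=freq, power=peak_power,
                     theta_phase=float(scal.phase[j]), bandwidth=bandwidth,
                     snr=snr, passed_qc=not reasons, qc_reasons=reasons)


def total_gamma_power(scal: Scalogram,
                      criteria: QCCriteria = QCCriteria()) -> float:
    """Sum of power over the gamma band and all phases inside the COI."""
    lo, hi = criteria.gamma_band
    rows = (scal.frequencies >= lo) & (scal.frequencies <= hi)
    return float(np.sum(scal.power[rows] * scal.coi_mask[rows]))


def welch_psd(trace, fs: float, n_segments: int = 40,
              overlap: float = 0.5):
    """Welch PSD with ``n_segments`` segments at fractional ``overlap``.

    Segment length is ``floor(N / (n_segments/2 + 0.5))`` for 50% overlap
    so exactly ``n_segments`` windows fit.  Returns (freqs Hz, PSD).
    """
    x = np.asarray(trace, dtype=float)
    denom = n_segments * (1.0 - overlap) + overlap
    nperseg = int(np.floor(x.size / denom))
    if nperseg < 8:
        raise ValueError("trace too short for the requested segmentation")
    noverlap = int(np.floor(nperseg * overlap))
    return sps.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap)


def spike_phase_histogram(spikes, theta_freq: float, n_cycles: int,
                          t_start: float = 0.0, n_bins: int = 30):
    """Per-cycle-normalized phase histogram of spike times (ms).

    Returns (counts/n_cycles of shape (n_bins,), n_excluded) where
    excluded spikes fall outside the analyzed window.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    spikes = np.asarray(spikes, dtype=float)
    period = 1000.0 / theta_freq
    t_end = t_start + n_cycles * period
    inside = (spikes >= t_start) & (spikes < t_end)
    phase = ((spikes[inside] - t_start) % period) / period
    hist, _ = np.histogram(phase, bins=n_bins, range=(0.0, 1.0))
    return hist / n_cycles, int(np.sum(~inside))


def isi_frequency_histogram(spikes, n_cycles: int, bin_hz: float = 10.0,
                            max_hz: float = 500.0):
    """Instantaneous-frequency (1000/ISI) histogram, per-cycle normalized.

    Returns (bin_edges Hz, counts / n_cycles).
    """
    spikes = np.asarray(spikes, dtype=float)
    edges = np.arange(0.0, max_hz + bin_hz, bin_hz)
    if spikes.size < 2:
        return edges, np.zeros(edges.size - 1)
    isi = np.diff(spikes)
    freq = 1000.0 / isi[isi > 0]
    hist, _ = np.histogram(freq, bins=edges)
    return edges, hist / n_cycles


def population_spike_histogram(spike_trains, bin_ms: float = 1.0,
                               t_start: float = 0.0,
                               t_stop: float | None = None):
    """Pooled spike-time histogram across cells.

    Returns (bin centers ms, counts).
    """
    all_sp = np.concatenate([np.asarray(s) for s in spike_trains]) \
        if len(spike_trains) else np.empty(0)
    if t_stop is None:
        t_stop = all_sp.max() + bin_ms if all_sp.size else bin_ms
    edges = np.arange(t_start, t_stop + bin_ms, bin_ms)
    hist, _ = np.histogram(all_sp, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), hist


def histogram_autocorr_frequency(hist, bin_ms: float,
                                 min_lag_ms: float = 3.0,
                                 max_lag_ms: float = 100.0,
                                 min_height: float = 0.05,
                                 detrend_ms: float | None = 7.0) -> float | None:
    """Frequency implied by the first non-zero-lag autocorrelogram peak.

    The histogram is detrended with a ``detrend_ms`` moving average
    (removing the slow theta-envelope component that would otherwise
    swamp gamma-scale structure; None disables it), then its normalized
    autocorrelation is scanned for the first local maximum at lag >=
    ``min_lag_ms`` with normalized height >= ``min_height``.  Returns
    1000/lag in Hz, or None when no peak rises above the noise floor.
    """
    h = np.asarray(hist, dtype=float)
    if detrend_ms is not None and detrend_ms > bin_ms:
        win = max(2, int(round(detrend_ms / bin_ms)))
        h = h - np.convolve(h, np.ones(win) / win, mode="same")
    else:
        h = h - h.mean()
    if not np.any(h):
        return None
    ac = np.correlate(h, h, mode="full")[h.size - 1:]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    lo = max(1, int(round(min_lag_ms / bin_ms)))
    hi = min(ac.size - 1, int(round(max_lag_ms / bin_ms)))
    if hi <= lo:
        return None
    peaks, _ = sps.find_peaks(ac[:hi + 1], height=min_height,
                              prominence=min_height / 2.0)
    peaks = peaks[peaks >= lo]
    if peaks.size == 0:
        return None
    # sub-bin lag via parabolic interpolation around the peak
    k = int(peaks[0])
    if 0 < k < ac.size - 1:
        denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
        shift = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return 1000.0 / ((k + shift) * bin_ms)


def analyze_trace(trace, fs: float, theta_freq: float = 8.0,
                  criteria: QCCriteria = QCCriteria(),
                  prefilter: bool = True) -> dict:
    """Full per-trace pipeline: scalogram -> peak -> totals.

    Returns a dict with the scalogram, the GammaPeak, and the total
    gamma-band power within the cone of influence.
    """
    scal = cycle_average_scalogram(trace, fs, theta_freq, criteria,
                                   prefilter=prefilter)
    peak = find_gamma_peak(scal, criteria)
    total = total_gamma_power(scal, criteria)
    return {"scalogram": scal, "peak": peak, "total_gamma_power": total}
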