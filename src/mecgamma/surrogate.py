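"""Surrogate theta-nested gamma recordings with known ground truth.

These generators produce what the analysis pipeline expects to see in
clamp recordings — an 8 Hz raised-cosine envelope carrying a gamma-band
carrier, white noise, occasional large artifacts, and gamma-locked spike
trains with cycle skipping — but with every "true" quantity (carrier
frequency, artifact cycles, firing probability) known exactly, so
frequency recovery and quality control can be tested end to end without
running the network model.

The envelope is the same raised cosine used for the simulated optogenetic
drive, so surrogates and simulations share the theta phase convention.
Artifacts are single-sample +/-5,000 pA deflections, unambiguously above
the 3,000 pA exclusion criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurrogateSpec", "generate_current_trace", "generate_spike_trains"]

ARTIFACT_AMPLITUDE = 5000.0  # pA


@dataclass(frozen=True)
class SurrogateSpec:
    theta_freq: float = 8.0  # Hz
    gamma_freq: float = 100.0  # Hz
    gamma_peak_amplitude: float = 100.0  # pA at the envelope crest
    noise_sd: float = 10.0  # pA, white
    artifact_rate: float = 0.0  # expected artifacts per 40 cycles
    n_cycles: int = 41
    fs: float = 10000.0  # Hz sampling rate
    #: probability that a cell fires on a given gamma crest inside the
    #: participation window (geometric cycle skipping)
    p_fire: float = 0.5
    #: theta-phase window (fractions of the cycle) where cells may fire
    participation_window: tuple = (0.25, 0.75)
    spike_jitter_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_freq <= self.theta_freq:
            raise ValueError("gamma_freq must exceed theta_freq")
        if self.gamma_peak_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not 0.0 <= self.p_fire <= 1.0:
            raise ValueError("p_fire must lie in [0, 1]")


def generate_current_trace(spec: SurrogateSpec):
    """Theta-nested gamma current trace plus its ground truth.

    Returns ``(trace pA, truth)`` where truth records the carrier
    frequency, the injected artifact cycle indices, and the per-cycle
    envelope peak amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    period = spec.fs / spec.theta_freq
    n = int(round(spec.n_cycles * period))
    t = np.arange(n) / spec.fs
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * spec.theta_freq * t))
    trace = spec.gamma_peak_amplitude * env \
        * np.sin(2.0 * np.pi * spec.gamma_freq * t)
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, size=n)

    artifact_cycles: list[int] = []
    n_art = rng.poisson(spec.artifact_rate * spec.n_cycles / 40.0)
    # never contaminate cycle 0 (excluded anyway) and keep cycles distinct
    candidates = list(range(1, spec.n_cycles))
    rng.shuffle(candidates)
    for c in candidates[:n_art]:
        samp = int(round(period))
        idx = c * samp + int(rng.integers(0, samp))
        trace[idx] += ARTIFACT_AMPLITUDE * (1 if rng.random() < 0.5 else -1)
        artifact_cycles.append(c)

    truth = {
        "gamma_freq": spec.gamma_freq,
        "artifact_cycles": sorted(artifact_cycles),
        "peak_amplitude": spec.gamma_peak_amplitude,
    }
    return trace, truth


def generate_spike_trains(spec: SurrogateSpec, n_cells: int):
    """Gamma-crest-locked spike trains with geometric cycle skipping.

    Spikes sit on gamma-carrier crests (sin phase pi/2) whose theta phase
    falls inside the participation window; each crest is occupied
    independently with probability ``p_fire`` per cell, with optional
    Gaussian jitter.  The resulting instantaneous-frequency histogram
    concentrates at the gamma frequency and its integer subharmonics.
    """
    rng = np.random.default_rng(spec.seed + 1)
    theta_period = 1000.0 / spec.theta_freq
    gamma_period = 1000.0 / spec.gamma_freq
    duration = spec.n_cycles * theta_period
    # gamma crest times: sin(2 pi f t) = 1 at t = (k + 1/4) / f
    crests = (np.arange(int(duration / gamma_period)) + 0.25) * gamma_period
    phase = (crests % theta_period) / theta_period
    lo, hi = spec.participation_window
    crests = crests[(phase >= lo) & (phase < hi)]
    trains = []
    for _ in range(n_cells):
        keep = rng.random(crests.size) < spec.p_fire
        sp = crests[keep]
        if spec.spike_jitter_ms > 0:
            sp = np.sort(sp + rng.normal(0, spec.spike_jitter_ms, sp.size))
        trains.append(sp)
    return trains
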