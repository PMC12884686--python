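"""Simulation campaigns over the excitation-inhibition parameter space.

Three campaigns mirror the study design:

* :func:`sweep_ei` — vary the E->I conductance axis at fixed I->E scale
  over several connectivity seeds and tabulate the gamma peak of every
  E-readout clamp trace;
* :func:`heatmap_ei_ie` — factorial sweep of E->I strength and the I->E
  log-normal mean scale;
* :func:`shunting_control` — swap the I->I GABA_A reversal to -55 mV
  (shunting) and ask whether any quality-controlled gamma peak survives
  with and without E->I coupling.

Each run contributes one table row per readout cell.  The runtime-noise
seed of a run is derived from its connectivity seed, so a campaign is
fully determined by its seed list.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (QCCriteria, cycle_average_scalogram, find_gamma_peak,
                       total_gamma_power)
from .cells import ECellParams, PVCellParams
from .network import ConnectivitySpec, build_network
from .simulate import DriveSpec, SynapseParams, run_simulation

__all__ = [
    "CampaignProfile",
    "RegimeLabel",
    "run_condition",
    "sweep_ei",
    "heatmap_ei_ie",
    "shunting_control",
    "classify_regime",
    "summarize_sweep",
]

SWEEP_COLUMNS = ["ei_gmax", "ie_scale", "gaba_reversal", "seed", "readout",
                 "peak_freq", "peak_power", "total_gamma_power", "snr",
                 "bandwidth", "passed_qc", "qc_reasons"]


@dataclass(frozen=True)
class CampaignProfile:
    """Problem sizes and analysis settings for a campaign.

    ``full()`` reproduces the published conditions (40 analyzed cycles);
    ``ci()`` is a reduced profile (10 analyzed cycles) for fast runs.
    """

    n_cycles: int = 41
    dt: float = 0.025
    record_dt: float = 0.1
    criteria: QCCriteria = field(default_factory=QCCriteria.thy1)
    pv: PVCellParams = field(default_factory=PVCellParams)
    ecell: ECellParams = field(default_factory=ECellParams)
    prefilter: bool = True

    @classmethod
    def full(cls) -> "CampaignProfile":
        return cls(n_cycles=41)

    @classmethod
    def ci(cls) -> "CampaignProfile":
        return cls(n_cycles=11)


def run_condition(ei_gmax: float, seed: int, *, ie_scale: float = 2.5,
                  gaba_reversal: float = -75.0,
                  profile: CampaignProfile = CampaignProfile(),
                  base_spec: ConnectivitySpec | None = None,
                  return_result: bool = False):
    """Build, simulate and analyze one (condition, seed) cell.

    Returns the per-readout rows (list of dicts); with ``return_result``
    also the :class:`SimulationResult` for spike-train analyses.
    """
    base = base_spec or ConnectivitySpec()
    spec = dataclasses.replace(base, seed=seed, ei_gmax=ei_gmax,
                               ie_weight_mean_scale=ie_scale)
    graph = build_network(spec)
    syn = SynapseParams(ii_e_rev=gaba_reversal)
    drive = DriveSpec(n_cycles=profile.n_cycles)
    res = run_simulation(graph, drive, syn, dt=profile.dt, seed=seed,
                         pv=profile.pv, ecell=profile.ecell,
                         record_dt=profile.record_dt)
    fs = 1000.0 / res.record_dt
    rows = []
    for k, trace in enumerate(res.clamp_e):
        scal = cycle_average_scalogram(trace, fs, res.theta_freq,
                                       profile.criteria,
                                       prefilter=profile.prefilter)
        peak = find_gamma_peak(scal, profile.criteria)
        rows.append({
            "ei_gmax": ei_gmax, "ie_scale": ie_scale,
            "gaba_reversal": gaba_reversal, "seed": seed,
            "readout": int(res.readout_e[k]),
            "peak_freq": peak.frequency if peak.passed_qc else np.nan,
            "peak_power": peak.power,
            "total_gamma_power": total_gamma_power(scal, profile.criteria),
            "snr": peak.snr, "bandwidth": peak.bandwidth,
            "passed_qc": peak.passed_qc,
            "qc_reasons": ";".join(peak.qc_reasons),
        })
    if return_result:
        return rows, res
    return rows


def sweep_ei(conductances, seeds, *,
             profile: CampaignProfile = CampaignProfile(),
             base_spec: ConnectivitySpec | None = None,
             on_error: str = "record") -> pd.DataFrame:
    """E->I conductance sweep; one row per (conductance, seed, readout).

    Individual run failures are recorded as all-NaN rows and the campaign
    continues (set ``on_error='raise'`` to propagate).
    """
    if len(conductances) < 1:
        raise ValueError("need at least one conductance value")
    rows = []
    for g in conductances:
        for seed in seeds:
            try:
                rows.extend(run_condition(float(g), int(seed),
                                          profile=profile,
                                          base_spec=base_spec))
            except Exception:
                if on_error == "raise":
                    raise
                rows.append({"ei_gmax": float(g), "ie_scale": 2.5,
                             "gaba_reversal": -75.0, "seed": int(seed),
                             "readout": -1, "peak_freq": np.nan,
                             "peak_power": np.nan,
                             "total_gamma_power": np.nan, "snr": np.nan,
                             "bandwidth": np.nan, "passed_qc": False,
                             "qc_reasons": "run-failed"})
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def heatmap_ei_ie(ei_grid, ie_grid, seeds, *,
                  profile: CampaignProfile = CampaignProfile(),
                  base_spec: ConnectivitySpec | None = None) -> pd.DataFrame:
    """Factorial E->I x I->E campaign (the two-axis generalization)."""
    if not len(ei_grid) or not len(ie_grid):
        raise ValueError("both grids must be nonempty")
    rows = []
    for g in ei_grid:
        for s in ie_grid:
            for seed in seeds:
                try:
                    rows.extend(run_condition(float(g), int(seed),
                                              ie_scale=float(s),
                                              profile=profile,
                                              base_spec=base_spec))
                except Exception:
                    rows.append({"ei_gmax": float(g), "ie_scale": float(s),
                                 "gaba_reversal": -75.0, "seed": int(seed),
                                 "readout": -1, "peak_freq": np.nan,
                                 "peak_power": np.nan,
                                 "total_gamma_power": np.nan,
                                 "snr": np.nan, "bandwidth": np.nan,
                                 "passed_qc": False,
                                 "qc_reasons": "run-failed"})
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def shunting_control(seeds, *, ei_values=(0.0, 60.0),
                     gaba_reversal: float = -55.0,
                     profile: CampaignProfile = CampaignProfile(),
                     base_spec: ConnectivitySpec | None = None):
    """Shunting I->I variant: gamma presence per E->I condition.

    Only the I->I reversal changes; I->E keeps -65 mV.  Returns
    (SweepTable, {ei_gmax: any QC-passing readout?}).
    """
    rows = []
    for g in ei_values:
        for seed in seeds:
            rows.extend(run_condition(float(g), int(seed),
                                      gaba_reversal=gaba_reversal,
                                      profile=profile, base_spec=base_spec))
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    presence = {g: bool(table.loc[table.ei_gmax == g, "passed_qc"].any())
                for g in ei_values}
    return table, presence


@dataclass
class RegimeLabel:
    """ING- vs PING-dominated classification of interneuron firing."""

    label: str  # "ING-dominated" | "PING-dominated" | "undefined"
    spikes_per_burst: float
    interburst_ms: float
    reason: str = ""


def classify_regime(spike_trains_i, gamma_freq: float, *,
                    burst_threshold: float = 1.5,
                    interburst_tol: float = 0.5,
                    min_spikes: int = 50) -> RegimeLabel:
    """Classify interneuron firing as ING- or PING-dominated.

    Spikes of each cell are grouped into bursts using a gap of half the
    network gamma period; the network is PING-dominated when active cells
    average more than ``burst_threshold`` spikes per burst and the median
    intraburst interspike interval is well below the network period —
    i.e., the rhythm is paced by the interburst interval rather than the
    interspike interval.  ``interburst_tol`` sets "well below" as a
    fraction of the period.
    """
    if not np.isfinite(gamma_freq) or gamma_freq <= 0:
        return RegimeLabel("undefined", np.nan, np.nan,
                           "no quality-controlled gamma peak")
    period = 1000.0 / gamma_freq
    gap = period / 2.0
    per_burst = []
    intra_isis = []
    interbursts = []
    n_spikes = 0
    for sp in spike_trains_i:
        sp = np.asarray(sp)
        if sp.size < 2:
            continue
        n_spikes += sp.size
        isi = np.diff(sp)
        burst_breaks = isi >= gap
        sizes = np.diff(np.flatnonzero(
            np.concatenate(([True], burst_breaks, [True]))))
        per_burst.append(sizes.mean())
        intra_isis.extend(isi[~burst_breaks])
        starts = sp[np.concatenate(([True], burst_breaks))]
        if starts.size > 1:
            interbursts.extend(np.diff(starts))
    if n_spikes < min_spikes or not per_burst:
        return RegimeLabel("undefined", np.nan, np.nan,
                           "insufficient interneuron spikes")
    spb = float(np.mean(per_burst))
    ibi = float(np.median(interbursts)) if interbursts else np.nan
    intra = float(np.median(intra_isis)) if intra_isis else np.nan
    ping = spb > burst_threshold and np.isfinite(intra) \
        and intra < interburst_tol * period
    return RegimeLabel("PING-dominated" if ping else "ING-dominated",
                       spb, ibi)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition medians and interquartile range across seeds/readouts."""
    def q1(x):
        return x.quantile(0.25)

    def q3(x):
        return x.quantile(0.75)

    return (table[table.passed_qc]
            .groupby(["ei_gmax", "ie_scale", "gaba_reversal"])
            .agg(median_freq=("peak_freq", "median"),
                 freq_q1=("peak_freq", q1), freq_q3=("peak_freq", q3),
                 median_power=("peak_power", "median"),
                 median_total_power=("total_gamma_power", "median"),
                 n=("peak_freq", "count"))
            .reset_index())
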