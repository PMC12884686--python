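"""Shared fixtures.

The expensive network simulations are run once per session at a reduced
problem size (11 theta cycles: 1 discarded + 10 analyzed) and shared by
the acceptance tests; individual unit tests build their own tiny
problems.
"""

from __future__ import annotations

import numpy as np
import pytest

from mecgamma.analysis import (QCCriteria, cycle_average_scalogram,
                               find_gamma_peak, population_spike_histogram)
from mecgamma.network import ConnectivitySpec, build_network
from mecgamma.simulate import DriveSpec, SynapseParams, run_simulation

SEEDS = (1, 2, 3)
EI_GRID = (0.0, 6.0, 12.0, 24.0, 60.0)
CI_CYCLES = 11


def _run_and_analyze(ei_gmax, seed, syn=None, cycles=CI_CYCLES):
    spec = ConnectivitySpec(seed=seed, ei_gmax=ei_gmax)
    graph = build_network(spec)
    res = run_simulation(graph, DriveSpec(n_cycles=cycles),
                         syn or SynapseParams(), seed=seed)
    fs = 1000.0 / res.record_dt
    peaks = [find_gamma_peak(cycle_average_scalogram(
        tr, fs, res.theta_freq, QCCriteria.thy1(), prefilter=True))
        for tr in res.clamp_e]
    return {
        "result": res,
        "peaks": peaks,
        "median_freq": float(np.median([p.frequency for p in peaks])),
        "median_power": float(np.median([p.power for p in peaks])),
        "qc_pass": sum(p.passed_qc for p in peaks),
    }


@pytest.fixture(scope="session")
def ing_runs_full():
    """Pure-ING condition (E->I = 0) at the full 41-cycle problem size."""
    return {s: _run_and_analyze(0.0, s, cycles=41) for s in SEEDS}


@pytest.fixture(scope="session")
def ei_sweep_runs():
    """{(ei_gmax, seed): analyzed run} over the E->I grid, reduced size."""
    return {(g, s): _run_and_analyze(g, s) for g in EI_GRID for s in SEEDS}


@pytest.fixture(scope="session")
def shunting_runs():
    """Shunting I->I variant at the two sweep endpoints, two seeds."""
    syn = SynapseParams.shunting()
    return {(g, s): _run_and_analyze(g, s, syn=syn)
            for g in (0.0, 60.0) for s in (1, 2)}


def population_histogram_of(res, pop="e", bin_ms=1.0):
    trains = res.spikes_e if pop == "e" else res.spikes_i
    period = 1000.0 / res.theta_freq
    return population_spike_histogram(trains, bin_ms, period, res.duration)
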