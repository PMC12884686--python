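"""Network simulation under simulated 8 Hz optogenetic conductance drive.

The drive is a raised-cosine ("sinusoid biased to have only positive
values") conductance reversing at 0 mV; each theta cycle starts at the
trough (g = 0).  Interneurons receive per-cell peak conductances drawn
Normal(4, 0.4) nS (truncated at 0), stellate cells a uniform 3 nS peak.
Five readout cells per population are voltage-clamped (default 0 mV); the
recorded trace is the synaptic current onto them, which at 0 mV holding is
dominated by GABA_A (inhibitory) currents.

Chemical synapses are conductance-based: bi-exponential for the two GABA_A
classes (I->I rise 0.3 ms / decay 4 ms, I->E rise 0.4 ms / decay 6 ms),
normalized so a unit-weight spike produces a 1 nS peak; single-exponential
(decay 1 ms) for the AMPA E->I class.  Spikes propagate after per-edge
delays drawn uniform on 0.6-1.0 ms, rounded to the integration grid.
Gap junctions pass ohmic current g*(V_peer - V_self) between interneuron
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import cells
from ._kernel import integrate_network
from .cells import (DEFAULT_E_NOISE, DEFAULT_I_NOISE, ECellParams,
                    OUProcessParams, PVCellParams, jitter_conductances)
from .network import NetworkGraph

__all__ = [
    "DriveSpec",
    "SynapseParams",
    "SimulationResult",
    "theta_drive",
    "biexp_peak_time",
    "biexp_normalization",
    "BiExpSynapse",
    "SingleExpSynapse",
    "gap_junction_current",
    "run_simulation",
    "integrate_single_pv",
]

#: offset separating the runtime-noise stream from the connectivity stream
RUNTIME_SEED_OFFSET = 9973


@dataclass(frozen=True)
class DriveSpec:
    """Simulated optogenetic theta-conductance drive."""

    freq: float = 8.0  # Hz
    peak_i_mean: float = 4.0  # nS, per-interneuron peak ~ N(mean, sd)
    peak_i_sd: float = 0.4  # nS
    peak_e: float = 3.0  # nS, per stellate cell
    e_rev: float = 0.0  # mV
    n_cycles: int = 41  # 1 discarded by the analysis + 40 analyzed

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.freq

    @property
    def duration_ms(self) -> float:
        return self.n_cycles * self.period_ms


def theta_drive(spec: DriveSpec, t, peak):
    """Raised-cosine conductance ``peak * (1 - cos(2 pi f t)) / 2`` (nS)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * spec.freq * t / 1000.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SynapseParams:
    """Time constants (ms) and reversal potentials (mV) per synapse class."""

    ii_tau_rise: float = 0.3
    ii_tau_decay: float = 4.0
    ii_e_rev: float = -75.0  # -55 mV in the shunting variant
    ie_tau_rise: float = 0.4
    ie_tau_decay: float = 6.0
    ie_e_rev: float = -65.0
    ei_tau_decay: float = 1.0
    ei_e_rev: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.ii_tau_rise < self.ii_tau_decay):
            raise ValueError("II synapse requires 0 < rise < decay")
        if not (0 < self.ie_tau_rise < self.ie_tau_decay):
            raise ValueError("IE synapse requires 0 < rise < decay")
        if self.ei_tau_decay <= 0:
            raise ValueError("EI decay must be positive")

    @classmethod
    def shunting(cls, e_rev: float = -55.0) -> "SynapseParams":
        """Shunting I->I variant; other classes keep their reversals."""
        return cls(ii_e_rev=e_rev)


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of a difference-of-exponentials conductance (ms)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) \
        * math.log(tau_decay / tau_rise)


def biexp_normalization(tau_rise: float, tau_decay: float) -> float:
    """Factor making the bi-exponential peak equal the synaptic weight."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


class BiExpSynapse:
    """Reference bi-exponential conductance state (difference of
    exponentials, peak-normalized).  Mirrors the compiled kernel's synapse
    arithmetic for unit testing and single-cell work."""

    def __init__(self, tau_rise: float, tau_decay: float):
        if not 0 < tau_rise < tau_decay:
            raise ValueError("requires 0 < rise < decay")
        self.tau_rise, self.tau_decay = tau_rise, tau_decay
        self.norm = biexp_normalization(tau_rise, tau_decay)
        self.a = 0.0  # rising component
        self.b = 0.0  # decaying component

    @property
    def g(self) -> float:
        return self.b - self.a

    def step(self, dt: float, incoming_weight: float = 0.0) -> float:
        """Deliver ``incoming_weight`` (nS, summed over arriving spikes),
        return the conductance for this step, then decay."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if incoming_weight:
            self.a += incoming_weight * self.norm
            self.b += incoming_weight * self.norm
        g = self.g
        self.a *= math.exp(-dt / self.tau_rise)
        self.b *= math.exp(-dt / self.tau_decay)
        return g


class SingleExpSynapse:
    """Reference single-exponential conductance state."""

    def __init__(self, tau_decay: float):
        if tau_decay <= 0:
            raise ValueError("decay must be positive")
        self.tau_decay = tau_decay
        self.g = 0.0

    def step(self, dt: float, incoming_weight: float = 0.0) -> float:
        if dt <= 0:
            raise ValueError("dt must be positive")
        if incoming_weight:
            self.g += incoming_weight
        g = self.g
        self.g *= math.exp(-dt / self.tau_decay)
        return g


def gap_junction_current(v_self, v_peer, g):
    """Ohmic electrical-synapse current ``g (v_peer - v_self)`` in pA."""
    if np.any(np.asarray(g) < 0):
        raise ValueError("gap conductance must be nonnegative")
    return g * (np.asarray(v_peer, dtype=float) - v_self)


@dataclass
class SimulationResult:
    """Spike times, clamp currents and metadata of one network run."""

    dt: float
    record_dt: float
    duration: float
    theta_freq: float
    n_cycles: int
    spikes_i: list  # per I cell, strictly increasing spike times (ms)
    spikes_e: list
    clamp_i: np.ndarray  # (n_readout, n_rec) pA
    clamp_e: np.ndarray
    drive: np.ndarray  # normalized drive waveform at record times
    readout_i: np.ndarray
    readout_e: np.ndarray
    seed: int
    runtime_seed: int
    holding_mv: float
    meta: dict = field(default_factory=dict)

    @property
    def record_times(self) -> np.ndarray:
        return np.arange(self.clamp_e.shape[1]) * self.record_dt

    def all_spikes(self, pop: str) -> np.ndarray:
        trains = self.spikes_i if pop == "i" else self.spikes_e
        return np.sort(np.concatenate([s for s in trains] or [np.empty(0)]))

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("dt", "record_dt", "duration", "theta_freq",
                         "n_cycles", "seed", "runtime_seed", "holding_mv"):
                f.attrs[name] = getattr(self, name)
            for pop, trains in (("i", self.spikes_i), ("e", self.spikes_e)):
                flat = np.concatenate(trains) if trains else np.empty(0)
                ptr = np.cumsum([0] + [len(s) for s in trains])
                f.create_dataset(f"spikes/{pop}/times", data=flat)
                f.create_dataset(f"spikes/{pop}/indptr", data=ptr)
            f.create_dataset("clamp/i", data=self.clamp_i)
            f.create_dataset("clamp/e", data=self.clamp_e)
            f.create_dataset("drive", data=self.drive)
            f.create_dataset("readout/i", data=self.readout_i)
            f.create_dataset("readout/e", data=self.readout_e)

    @classmethod
    def from_hdf5(cls, path) -> "SimulationResult":
        with h5py.File(path, "r") as f:
            trains = {}
            for pop in ("i", "e"):
                flat = f[f"spikes/{pop}/times"][...]
                ptr = f[f"spikes/{pop}/indptr"][...]
                trains[pop] = [flat[ptr[k]:ptr[k + 1]]
                               for k in range(len(ptr) - 1)]
            return cls(
                dt=float(f.attrs["dt"]),
                record_dt=float(f.attrs["record_dt"]),
                duration=float(f.attrs["duration"]),
                theta_freq=float(f.attrs["theta_freq"]),
                n_cycles=int(f.attrs["n_cycles"]),
                spikes_i=trains["i"], spikes_e=trains["e"],
                clamp_i=f["clamp/i"][...], clamp_e=f["clamp/e"][...],
                drive=f["drive"][...],
                readout_i=f["readout/i"][...], readout_e=f["readout/e"][...],
                seed=int(f.attrs["seed"]),
                runtime_seed=int(f.attrs["runtime_seed"]),
                holding_mv=float(f.attrs["holding_mv"]),
            )


def _edges_to_csr(edges: dict, n_pre: int, dt: float):
    """Group edges by presynaptic cell into CSR arrays; delays in steps."""
    pre = np.asarray(edges["pre"], dtype=np.int64)
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    post = np.asarray(edges["post"], dtype=np.int64)[order]
    w = np.asarray(edges["weight"], dtype=np.float64)[order]
    dsteps = np.rint(np.asarray(edges["delay"], dtype=np.float64)[order]
                     / dt).astype(np.int64)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, post, w, dsteps


def _gap_to_csr(graph: NetworkGraph):
    """Directed CSR over I cells from the unordered gap-junction pairs."""
    a = np.concatenate([graph.gap_a, graph.gap_b]).astype(np.int64)
    b = np.concatenate([graph.gap_b, graph.gap_a]).astype(np.int64)
    g = np.concatenate([graph.gap_g, graph.gap_g]).astype(np.float64)
    order = np.argsort(a, kind="stable")
    a, b, g = a[order], b[order], g[order]
    indptr = np.zeros(graph.n_i + 1, dtype=np.int64)
    np.add.at(indptr, a + 1, 1)
    return np.cumsum(indptr), b, g


def run_simulation(graph: NetworkGraph, drive: DriveSpec = DriveSpec(),
                   syn: SynapseParams = SynapseParams(), *,
                   dt: float = 0.025, seed: int = 0,
                   pv: PVCellParams | None = None,
                   ecell: ECellParams | None = None,
                   ou_e: OUProcessParams = DEFAULT_E_NOISE,
                   ou_i: OUProcessParams = DEFAULT_I_NOISE,
                   record_dt: float = 0.1,
                   holding_mv: float = 0.0,
                   include_drive_in_clamp: bool = False) -> SimulationResult:
    """Integrate the network for ``drive.n_cycles`` theta cycles.

    Two RNG streams are used: per-cell heterogeneity (drive peaks, E-cell
    conductance jitter) follows the *connectivity* seed stored in the
    graph, so the same network always has the same cells; initial
    conditions and the OU noise path follow ``seed`` (runtime stream).
    Identical (graph, seed, dt) give bit-identical results on one machine.
    """
    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must be in (0, 0.05] ms")
    pv = pv or PVCellParams()
    ecell = ecell or ECellParams()
    n_i, n_e = graph.n_i, graph.n_e

    het_seed = graph.spec.seed if graph.spec is not None else seed
    rng_het = np.random.default_rng(int(het_seed))
    peak_i = np.clip(rng_het.normal(drive.peak_i_mean, drive.peak_i_sd,
                                    size=n_i), 0.0, None)
    peak_e = np.full(n_e, float(drive.peak_e))
    gna_i, gkv1_i, gkv3_i, gl_i = jitter_conductances(
        (pv.g_na, pv.g_kv1, pv.g_kv3, pv.g_leak), pv.jitter_cv, n_i, rng_het)
    gna_e, gk_e, gl_e = jitter_conductances(
        (ecell.g_na, ecell.g_k, ecell.g_leak), ecell.jitter_cv, n_e, rng_het)

    runtime_seed = (int(seed) + RUNTIME_SEED_OFFSET) % (2 ** 31 - 1)
    rng_rt = np.random.default_rng(runtime_seed)
    v_i = rng_rt.uniform(-70.0, -60.0, size=n_i)
    v_e = rng_rt.uniform(-70.0, -60.0, size=n_e)
    gates_i = {g: np.array([cells.gate_steady_state(pv.kinetics[g], v)
                            for v in v_i]) for g in cells.PV_GATES}
    rates_e = cells.hh_rates(v_e)
    gates_e = {g: a / (a + b) for g, (a, b) in rates_e.items()}
    gou_e = ou_e.mean_g + ou_e.sd_g * rng_rt.standard_normal(n_e)
    gou_i = ou_i.mean_g + ou_i.sd_g * rng_rt.standard_normal(n_e)

    clamped_i = np.zeros(n_i, dtype=np.bool_)
    clamped_i[graph.readout_i] = True
    clamped_e = np.zeros(n_e, dtype=np.bool_)
    clamped_e[graph.readout_e] = True
    v_i[clamped_i] = holding_mv
    v_e[clamped_e] = holding_mv

    period = drive.period_ms
    steps_per_cycle = int(round(period / dt))
    n_steps = drive.n_cycles * steps_per_cycle
    record_stride = max(1, int(round(record_dt / dt)))
    n_rec = (n_steps + record_stride - 1) // record_stride

    # normalize bi-exponential weights so the peak equals the edge weight
    ii = dict(graph.chem["II"])
    ii["weight"] = ii["weight"] * biexp_normalization(syn.ii_tau_rise,
                                                      syn.ii_tau_decay)
    ie = dict(graph.chem["IE"])
    ie["weight"] = ie["weight"] * biexp_normalization(syn.ie_tau_rise,
                                                      syn.ie_tau_decay)
    ii_csr = _edges_to_csr(ii, n_i, dt)
    ie_csr = _edges_to_csr(ie, n_i, dt)
    ei_csr = _edges_to_csr(graph.chem["EI"], n_e, dt)
    gap_csr = _gap_to_csr(graph)

    max_dsteps = max((int(c[3].max()) if len(c[3]) else 0)
                     for c in (ii_csr, ie_csr, ei_csr))
    nslots = max_dsteps + 2
    buf_ii = np.zeros((nslots, n_i))
    buf_ei = np.zeros((nslots, n_i))
    buf_ie = np.zeros((nslots, n_e))

    cap_i = n_i * (int(drive.duration_ms) + 2)
    cap_e = n_e * (int(drive.duration_ms) + 2)
    spk_t_i = np.empty(cap_i)
    spk_c_i = np.empty(cap_i, dtype=np.int64)
    spk_t_e = np.empty(cap_e)
    spk_c_e = np.empty(cap_e, dtype=np.int64)

    rec_i = np.zeros((len(graph.readout_i), n_rec))
    rec_e = np.zeros((len(graph.readout_e), n_rec))
    rec_drive = np.zeros(n_rec)

    kin = np.array([[pv.kinetics[g].theta, pv.kinetics[g].sigma1,
                     pv.kinetics[g].sigma2, pv.kinetics[g].k1,
                     pv.kinetics[g].k2,
                     1.0 if pv.kinetics[g].is_inactivation else 0.0]
                    for g in cells.PV_GATES])

    def ou_factors(p):
        decay = math.exp(-dt / p.tau)
        return decay, p.sd_g * math.sqrt(1.0 - decay * decay)

    dec_e, dif_e = ou_factors(ou_e)
    dec_i, dif_i = ou_factors(ou_i)

    nsp_i, nsp_e, err = integrate_network(
        n_steps, dt, record_stride,
        2.0 * np.pi * drive.freq / 1000.0,
        v_i, gates_i["m"], gates_i["h"], gates_i["n"], gates_i["a"],
        clamped_i, np.full(n_i, -1e9), peak_i,
        pv.cm, gna_i, gkv1_i, gkv3_i, gl_i,
        pv.e_na, pv.e_k, pv.e_leak, kin,
        v_e, gates_e["m"], gates_e["h"], gates_e["n"],
        clamped_e, np.full(n_e, -1e9), peak_e,
        ecell.cm, gna_e, gk_e, gl_e, ecell.e_na, ecell.e_k, ecell.e_leak,
        gou_e, gou_i, ou_e.mean_g, ou_e.sd_g, dec_e, dif_e, ou_e.e_rev,
        ou_i.mean_g, ou_i.sd_g, dec_i, dif_i, ou_i.e_rev,
        syn.ii_e_rev, syn.ie_e_rev, syn.ei_e_rev,
        math.exp(-dt / syn.ii_tau_rise), math.exp(-dt / syn.ii_tau_decay),
        math.exp(-dt / syn.ie_tau_rise), math.exp(-dt / syn.ie_tau_decay),
        math.exp(-dt / syn.ei_tau_decay),
        *ii_csr, *ie_csr, *ei_csr, *gap_csr,
        buf_ii, buf_ei, buf_ie,
        np.zeros(n_i), np.zeros(n_i), np.zeros(n_i),
        np.zeros(n_e), np.zeros(n_e),
        holding_mv, include_drive_in_clamp,
        graph.readout_i.astype(np.int64), graph.readout_e.astype(np.int64),
        rec_i, rec_e, rec_drive,
        spk_t_i, spk_c_i, spk_t_e, spk_c_e,
        runtime_seed,
    )
    if err[0] != 0.0:
        pop = "I" if err[1] == 0.0 else "E"
        raise RuntimeError(
            f"non-finite membrane potential in {pop} cell {int(err[2])} "
            f"at t = {err[3]:.3f} ms; reduce dt or check parameters")

    spikes_i = [spk_t_i[:nsp_i][spk_c_i[:nsp_i] == c] for c in range(n_i)]
    spikes_e = [spk_t_e[:nsp_e][spk_c_e[:nsp_e] == c] for c in range(n_e)]
    return SimulationResult(
        dt=dt, record_dt=record_stride * dt, duration=drive.duration_ms,
        theta_freq=drive.freq, n_cycles=drive.n_cycles,
        spikes_i=spikes_i, spikes_e=spikes_e,
        clamp_i=rec_i, clamp_e=rec_e, drive=rec_drive,
        readout_i=np.asarray(graph.readout_i),
        readout_e=np.asarray(graph.readout_e),
        seed=int(seed), runtime_seed=runtime_seed, holding_mv=holding_mv,
        meta={"ei_gmax": graph.spec.ei_gmax if graph.spec else None,
              "ii_e_rev": syn.ii_e_rev},
    )


def integrate_single_pv(pv: PVCellParams, g_drive, duration: float,
                        dt: float = 0.025, v0: float = -65.0,
                        syn_g=None, syn_e_rev: float = -75.0):
    """Pure-Python single-interneuron integration (reference path).

    ``g_drive`` is a constant conductance (nS) or a callable of time (ms);
    ``syn_g`` optionally gives a synaptic conductance waveform (callable).
    Uses the same staggered exponential-Euler scheme as the network kernel
    but built from the public rate functions, so the two implementations
    can be cross-checked.  Returns (times, v, spike_times).
    """
    n = int(round(duration / dt))
    g_fn = g_drive if callable(g_drive) else (lambda t: g_drive)
    state = cells.pv_steady_state(pv, v0)
    gates = dict(state.gates)
    v = v0
    vs = np.empty(n)
    spikes = []
    last = -1e9
    for k in range(n):
        t = k * dt
        for g in cells.PV_GATES:
            kin = pv.kinetics[g]
            a = cells.alpha_rate(kin, v)
            b = cells.beta_rate(kin, v)
            if kin.is_inactivation:
                a, b = b, a
            xinf = a / (a + b)
            gates[g] = xinf + (gates[g] - xinf) * math.exp(-dt * (a + b))
        g_na = pv.g_na * gates["m"] ** 3 * gates["h"]
        g_k = pv.g_kv3 * gates["n"] ** 4 + pv.g_kv1 * gates["a"] ** 4
        gd = g_fn(t)
        gs = syn_g(t) if syn_g is not None else 0.0
        gtot = g_na + g_k + pv.g_leak + gd + gs
        num = (g_na * pv.e_na + g_k * pv.e_k + pv.g_leak * pv.e_leak
               + gd * 0.0 + gs * syn_e_rev)
        vinf = num / gtot
        v_new = vinf + (v - vinf) * math.exp(-dt * gtot / pv.cm)
        if v < 0.0 <= v_new:
            ts = t + dt * (0.0 - v) / (v_new - v)
            if ts - last > 1.0:
                spikes.append(ts)
                last = ts
        v = v_new
        vs[k] = v
    return np.arange(n) * dt, vs, np.asarray(spikes)
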