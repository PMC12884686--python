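"""Single-compartment conductance-based cell models.

Two cell types are defined:

* a fast-spiking, parvalbumin-positive (PV+) interneuron with a fast Na+
  current, two delayed-rectifier K+ currents (Kv1-like, slow, ``a^4``; and
  Kv3-like, fast, ``n^4``) and a leak — the "I" population;
* a stellate-like excitatory cell built from classic Hodgkin–Huxley rate
  functions with jittered conductances and Ornstein–Uhlenbeck (OU)
  conductance noise — the "E" population.

Units are fixed package-wide: mV, ms, nS, pF, pA (1 nS * 1 mV = 1 pA, so
``dV/dt = I[pA] / C[pF]`` is in mV/ms).

Gating kinetics
---------------
Every gate relaxes as ``dx/dt = open(V)(1-x) - close(V)x``.  The two rate
shapes are a linoid ("alpha") and an exponential ("beta"):

.. math::

    \\alpha(V) = k_1 |\\sigma_1| \\frac{u}{e^u - 1},\\quad
    u = \\frac{\\theta - V}{\\sigma_1}, \\qquad
    \\beta(V) = k_2 e^{V/\\sigma_2}.

The linoid is written in magnitude form so it is positive for either sign of
``sigma1``; the *signs* of ``sigma1`` and ``sigma2`` encode whether each rate
grows or decays with depolarization, which is what distinguishes activation
from inactivation phenomenology.  For ``sigma1 > 0`` the expression equals
the textbook ``k1 (theta - V) / (exp((theta - V)/sigma1) - 1)`` exactly,
with removable singularity ``k1 * sigma1`` at ``V = theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatingKinetics",
    "PVCellParams",
    "ECellParams",
    "OUProcessParams",
    "CellState",
    "alpha_rate",
    "beta_rate",
    "gate_derivative",
    "gate_steady_state",
    "pv_membrane_derivative",
    "e_membrane_derivative",
    "hh_rates",
    "ou_step",
    "PV_GATES",
    "E_GATES",
]

#: expansion threshold for the linoid removable singularity, in units of u
_LINOID_EPS = 1e-6


@dataclass(frozen=True)
class GatingKinetics:
    """Rate parameters of one Hodgkin–Huxley-style gating variable."""

    theta: float  # half-point of the linoid rate (mV)
    sigma1: float  # linoid slope (mV); sign selects rising/falling
    sigma2: float  # exponential slope (mV); sign selects rising/falling
    k1: float  # linoid rate scale (1/ms)
    k2: float  # exponential rate scale (1/ms)
    is_inactivation: bool = False  # if True, beta is the opening rate

    def __post_init__(self) -> None:
        if self.sigma1 == 0 or self.sigma2 == 0:
            raise ValueError("sigma1 and sigma2 must be nonzero")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rate scales k1, k2 must be positive")


def _linoid(u):
    """u / (e^u - 1), continuous through u = 0 (value 1)."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < _LINOID_EPS
    safe = np.where(small, 1.0, u)
    return np.where(small, 1.0 - u / 2.0 + u * u / 12.0,
                    safe / np.expm1(safe))


def alpha_rate(kin: GatingKinetics, v):
    """Linoid rate (1/ms); strictly positive, finite at ``v == theta``."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    u = (kin.theta - v) / kin.sigma1
    out = np.asarray(kin.k1 * abs(kin.sigma1) * _linoid(u))
    return out if out.ndim else float(out)


def beta_rate(kin: GatingKinetics, v):
    """Exponential rate ``k2 * exp(v / sigma2)`` (1/ms)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = kin.k2 * np.exp(v / kin.sigma2)
    return out if out.ndim else float(out)


def gate_steady_state(kin: GatingKinetics, v):
    """Fixed point of the gate at clamped voltage ``v``."""
    a, b = alpha_rate(kin, v), beta_rate(kin, v)
    return (b / (a + b)) if kin.is_inactivation else (a / (a + b))


def gate_derivative(kin: GatingKinetics, x, v):
    """dx/dt (1/ms) of a gate at value ``x`` and voltage ``v``.

    Activation gates obey ``alpha (1-x) - beta x``; gates flagged
    ``is_inactivation`` obey ``beta (1-x) - alpha x`` (opening and closing
    roles swapped).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("gate value must lie in [0, 1]")
    a, b = alpha_rate(kin, v), beta_rate(kin, v)
    if kin.is_inactivation:
        return b * (1.0 - x) - a * x
    return a * (1.0 - x) - b * x


# ---------------------------------------------------------------------------
# PV+ fast-spiking interneuron
# ---------------------------------------------------------------------------

PV_GATES = ("m", "h", "n", "a")

#: Gating-variable parameters of the fast-spiking interneuron model.
#: m: Na activation; h: Na inactivation (``beta (1-h) - alpha h``: the
#: exponential rate, falling with depolarization, opens the gate, while the
#: linoid — half-point -55.71 mV, slope 3.5 mV — closes it, giving
#: half-inactivation near -60 mV and ~2 ms recovery); n: Kv3 activation
#: (fast); a: Kv1 activation (slow).
PV_KINETICS: dict[str, GatingKinetics] = {
    "m": GatingKinetics(theta=-53.0, sigma1=4.0, sigma2=-13.0, k1=0.25, k2=0.1),
    "h": GatingKinetics(theta=-55.71, sigma1=3.5, sigma2=-20.0, k1=0.2,
                        k2=0.012, is_inactivation=True),
    "n": GatingKinetics(theta=5.9, sigma1=12.0, sigma2=-8.5, k1=1.0, k2=0.001),
    "a": GatingKinetics(theta=51.36, sigma1=12.0, sigma2=-80.0, k1=1.0, k2=0.02),
}


@dataclass(frozen=True)
class PVCellParams:
    """Fast-spiking interneuron membrane parameters.

    Maximal conductances and capacitance are calibrated so a ~4 nS
    theta-conductance drive (reversal 0 mV) elicits sustained gamma-band
    tonic firing with sub-millisecond spikes; they can be overridden from
    config.
    """

    cm: float = 50.0  # pF
    g_na: float = 14000.0  # nS
    g_kv1: float = 30.0  # nS
    g_kv3: float = 250.0  # nS
    g_leak: float = 6.0  # nS
    e_na: float = 50.0  # mV
    e_k: float = -90.0  # mV
    e_leak: float = -65.0  # mV
    #: relative SD of the Gaussian jitter applied per cell to the maximal
    #: conductances (population heterogeneity; truncated at 0)
    jitter_cv: float = 0.2
    kinetics: dict = field(default_factory=lambda: dict(PV_KINETICS))

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("membrane capacitance must be positive")
        for name in ("g_na", "g_kv1", "g_kv3", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        missing = set(PV_GATES) - set(self.kinetics)
        if missing:
            raise ValueError(f"missing gate kinetics: {sorted(missing)}")


@dataclass
class CellState:
    """Instantaneous state of one cell: voltage, gates, OU conductances."""

    v: float
    gates: dict
    ou_g: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.v):
            raise ValueError("membrane potential must be finite")
        for name, x in self.gates.items():
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name} outside [0, 1]")


def pv_steady_state(params: PVCellParams, v: float) -> CellState:
    """Gate fixed points at voltage ``v`` (standard initial condition)."""
    gates = {g: float(gate_steady_state(params.kinetics[g], v))
             for g in PV_GATES}
    return CellState(v=v, gates=gates)


def pv_membrane_derivative(params: PVCellParams, state: CellState,
                           g_drive: float = 0.0, i_syn: float = 0.0,
                           i_gap: float = 0.0) -> float:
    """dV/dt (mV/ms) of the interneuron.

    All intrinsic currents are in driving-force form ``g (E - V)`` so each
    current depolarizes when V is below its reversal; the conductance drive
    reverses at 0 mV; ``i_syn`` and ``i_gap`` are added as currents (pA,
    positive = depolarizing).
    """
    if params.cm <= 0:
        raise ValueError("membrane capacitance must be positive")
    v = state.v
    m, h, n, a = (state.gates[g] for g in PV_GATES)
    i_na = params.g_na * m ** 3 * h * (params.e_na - v)
    i_kv1 = params.g_kv1 * a ** 4 * (params.e_k - v)
    i_kv3 = params.g_kv3 * n ** 4 * (params.e_k - v)
    i_leak = params.g_leak * (params.e_leak - v)
    i_drive = g_drive * (0.0 - v)
    return (i_na + i_kv1 + i_kv3 + i_leak + i_drive + i_syn + i_gap) / params.cm


# ---------------------------------------------------------------------------
# Stellate (E) cell
# ---------------------------------------------------------------------------

E_GATES = ("m", "h", "n")


def hh_rates(v):
    """Classic Hodgkin–Huxley rate functions (rest near -65 mV).

    Returns ``{gate: (alpha, beta)}`` for gates m, h, n in 1/ms.  Here the
    conventional HH naming is kept: for h, alpha is the opening (recovery)
    rate and beta the closing rate.
    """
    v = np.asarray(v, dtype=float)
    am = 0.1 * 10.0 * _linoid(-(v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (np.exp(-(v + 35.0) / 10.0) + 1.0)
    an = 0.01 * 10.0 * _linoid(-(v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return {"m": (am, bm), "h": (ah, bh), "n": (an, bn)}


@dataclass(frozen=True)
class ECellParams:
    """Stellate-cell membrane parameters (HH-based).

    ``jitter_cv`` is the relative SD of the Gaussian used to jitter the
    maximal conductances across the population; jittered values are
    truncated at zero.
    """

    cm: float = 60.0  # pF
    g_na: float = 7000.0  # nS
    g_k: float = 1000.0  # nS
    g_leak: float = 12.0  # nS
    e_na: float = 50.0  # mV
    e_k: float = -77.0  # mV
    e_leak: float = -65.0  # mV
    jitter_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("membrane capacitance must be positive")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be nonnegative")


def jitter_conductances(nominals, cv: float, n: int,
                        rng: np.random.Generator):
    """Per-cell conductances jittered ``Normal(g, cv*g)``, truncated at 0.

    ``nominals`` is a sequence of nominal values; returns one (n,) array
    per nominal.
    """
    cols = []
    for nominal in nominals:
        g = rng.normal(nominal, cv * nominal, size=n)
        cols.append(np.clip(g, 0.0, None))
    return tuple(cols)


def e_steady_state(params: ECellParams, v: float) -> CellState:
    rates = hh_rates(v)
    gates = {g: float(a / (a + b)) for g, (a, b) in rates.items()}
    return CellState(v=v, gates=gates)


def e_membrane_derivative(params: ECellParams, state: CellState,
                          g_drive: float = 0.0, i_syn: float = 0.0,
                          g_ou_e: float = 0.0, g_ou_i: float = 0.0,
                          e_ou_e: float = 0.0, e_ou_i: float = -75.0) -> float:
    """dV/dt (mV/ms) of the stellate cell.

    OU noise enters multiplicatively as conductances ``g(t) (E_rev - V)``
    with the excitatory process reversing at 0 mV and the inhibitory one at
    -75 mV.
    """
    if params.cm <= 0:
        raise ValueError("membrane capacitance must be positive")
    v = state.v
    m, h, n = (state.gates[g] for g in E_GATES)
    i_na = params.g_na * m ** 3 * h * (params.e_na - v)
    i_k = params.g_k * n ** 4 * (params.e_k - v)
    i_leak = params.g_leak * (params.e_leak - v)
    i_drive = g_drive * (0.0 - v)
    i_ou = g_ou_e * (e_ou_e - v) + g_ou_i * (e_ou_i - v)
    return (i_na + i_k + i_leak + i_drive + i_ou + i_syn) / params.cm


# ---------------------------------------------------------------------------
# Ornstein–Uhlenbeck conductance noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OUProcessParams:
    """Stationary OU conductance-noise process.

    Defaults follow the two processes used for the E population: mean
    0.9 nS, SD 0.02 nS; excitatory noise (reversal 0 mV) has tau =
    10.49 ms, inhibitory noise (reversal -75 mV) tau = 2.728 ms.
    """

    mean_g: float  # nS
    sd_g: float  # nS
    tau: float  # ms
    e_rev: float  # mV

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sd_g < 0:
            raise ValueError("sd_g must be nonnegative")


E_NOISE = OUProcessParams(mean_g=0.9, sd_g=0.02, tau=10.49, e_rev=0.0)
I_NOISE = OUProcessParams(mean_g=0.9, sd_g=0.02, tau=2.728, e_rev=-75.0)

#: Simulation defaults: same processes with the noise SD raised to 0.1 nS,
#: strong enough that the stellate population is fluctuation-driven (the
#: common theta drive alone must not synchronize it) while the stationary
#: mean conductances stay at 0.9 nS.
DEFAULT_E_NOISE = OUProcessParams(mean_g=0.9, sd_g=0.1, tau=10.49, e_rev=0.0)
DEFAULT_I_NOISE = OUProcessParams(mean_g=0.9, sd_g=0.1, tau=2.728,
                                  e_rev=-75.0)


def ou_step(params: OUProcessParams, g, dt: float, rng: np.random.Generator):
    """Advance the OU conductance by ``dt`` with the exact discretization.

    ``g' = mu + (g - mu) e^{-dt/tau} + sd sqrt(1 - e^{-2 dt/tau}) z`` with
    standard-normal z, so the stationary mean and SD are independent of dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = np.asarray(g, dtype=float)
    decay = math.exp(-dt / params.tau)
    diffuse = params.sd_g * math.sqrt(1.0 - decay * decay)
    z = rng.standard_normal(size=g.shape) if g.ndim else rng.standard_normal()
    out = params.mean_g + (g - params.mean_g) * decay + diffuse * z
    return out if np.ndim(out) else float(out)
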