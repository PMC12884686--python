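"""Random network construction for the E-I-I circuit.

The circuit has 100 inhibitory (I) fast-spiking interneurons and 400
excitatory (E) stellate cells.  Chemical synapse classes:

* ``II`` — I->I GABA_A, connection probability 0.30, fixed weight;
* ``IE`` — I->E GABA_A, probability 0.40, log-normal weights whose
  arithmetic mean is scaled by 2.5;
* ``EI`` — E->I AMPA, probability 0.30; the swept quantity ``ei_gmax`` is
  by default the *mean total* conductance per interneuron, divided by the
  expected in-degree (p_ei * n_e) to give the per-connection weight.

E cells are not connected to each other.  In addition each unordered pair
of interneurons forms a gap junction with probability 0.18.  Five readout
cells per population are flagged for voltage clamp: they receive afferents
like any other cell but have no outgoing chemical synapses and are excluded
from gap junctions by default (a clamped node would act as a current sink).

All sampling is driven by a single seed, so a given
:class:`ConnectivitySpec` always produces the identical graph.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "ConnectivitySpec",
    "NetworkGraph",
    "build_network",
    "sample_lognormal_weights",
]

CHEM_CLASSES = ("II", "IE", "EI")


@dataclass(frozen=True)
class ConnectivitySpec:
    n_i: int = 100
    n_e: int = 400
    p_ii: float = 0.30
    p_ie: float = 0.40
    p_ei: float = 0.30
    p_gap: float = 0.18
    #: fixed per-connection I->I peak conductance (nS); calibrated default
    ii_weight: float = 0.3
    #: base arithmetic mean of the log-normal I->E weight (nS) before scaling
    ie_base_mean: float = 0.08
    #: multiplier applied to the log-normal I->E arithmetic mean
    ie_weight_mean_scale: float = 2.5
    #: coefficient of variation of the log-normal I->E weights
    ie_weight_cv: float = 1.0
    #: E->I conductance scale (nS) — the swept excitation axis.  Under the
    #: default "coincident" interpretation it is the peak gamma-volley
    #: AMPA conductance felt by one interneuron, converted to a
    #: per-connection weight by dividing by ``ei_coincident`` (the expected
    #: number of afferents coactive within the 1 ms AMPA decay at a volley);
    #: "total" divides by the expected in-degree p_ei*n_e instead, and
    #: "per_connection" applies it to each edge unscaled.
    ei_gmax: float = 0.0
    ei_interpretation: str = "coincident"
    ei_coincident: float = 18.0
    #: coefficient of variation of the log-normal E->I weights (0 = uniform)
    ei_weight_cv: float = 0.0
    delay_range: tuple = (0.6, 1.0)
    gap_g: float = 0.6  # nS per gap junction
    n_readout: int = 5
    #: include clamped readout interneurons in gap-junction sampling
    readout_gap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_i <= 0 or self.n_e <= 0:
            raise ValueError("population sizes must be positive")
        for p in ("p_ii", "p_ie", "p_ei", "p_gap"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must lie in [0, 1]")
        lo, hi = self.delay_range
        if not lo < hi:
            raise ValueError("delay_range must satisfy low < high")
        if self.ei_gmax < 0 or self.ii_weight < 0 or self.gap_g < 0:
            raise ValueError("conductances must be nonnegative")
        if self.ei_interpretation not in ("coincident", "total",
                                          "per_connection"):
            raise ValueError("unknown ei_interpretation")
        if self.n_readout > min(self.n_i, self.n_e):
            raise ValueError("more readouts than cells")


@dataclass
class NetworkGraph:
    """Sampled connectivity: chemical edge arrays per class + gap junctions.

    Pre/post indices are population-local (I cells 0..n_i-1, E cells
    0..n_e-1); the class name determines which population each side
    belongs to.

    Readout (clamped) cells keep their sampled outgoing chemical edges so
    the connectivity statistics stay exactly binomial, but those edges are
    inert because a clamped cell never spikes; readouts are excluded from
    gap junctions (which *would* leak current) unless ``readout_gap``.
    """

    n_i: int
    n_e: int
    chem: dict  # class -> dict(pre, post, weight, delay) of 1-D arrays
    gap_a: np.ndarray  # first I cell of each electrical pair (a < b)
    gap_b: np.ndarray
    gap_g: np.ndarray  # nS
    readout_i: np.ndarray  # clamped interneuron ids
    readout_e: np.ndarray  # clamped stellate ids
    spec: ConnectivitySpec | None = None

    def edge_count(self, cls: str) -> int:
        return len(self.chem[cls]["pre"])

    # -- serialization -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["n_i"], f.attrs["n_e"] = self.n_i, self.n_e
            if self.spec is not None:
                f.attrs["spec_json"] = json.dumps(
                    dataclasses.asdict(self.spec))
            for cls in CHEM_CLASSES:
                grp = f.create_group(f"chem/{cls}")
                for k, v in self.chem[cls].items():
                    grp.create_dataset(k, data=v)
            gap = f.create_group("gap")
            gap.create_dataset("a", data=self.gap_a)
            gap.create_dataset("b", data=self.gap_b)
            gap.create_dataset("g", data=self.gap_g)
            f.create_dataset("readout_i", data=self.readout_i)
            f.create_dataset("readout_e", data=self.readout_e)

    @classmethod
    def from_hdf5(cls, path) -> "NetworkGraph":
        with h5py.File(path, "r") as f:
            spec = None
            if "spec_json" in f.attrs:
                d = json.loads(f.attrs["spec_json"])
                d["delay_range"] = tuple(d["delay_range"])
                spec = ConnectivitySpec(**d)
            chem = {}
            for c in CHEM_CLASSES:
                grp = f[f"chem/{c}"]
                chem[c] = {k: grp[k][...] for k in grp}
            return cls(
                n_i=int(f.attrs["n_i"]), n_e=int(f.attrs["n_e"]),
                chem=chem,
                gap_a=f["gap/a"][...], gap_b=f["gap/b"][...],
                gap_g=f["gap/g"][...],
                readout_i=f["readout_i"][...],
                readout_e=f["readout_e"][...],
                spec=spec,
            )


def sample_lognormal_weights(n: int, base_mean: float, scale: float,
                             rng: np.random.Generator,
                             cv: float = 1.0) -> np.ndarray:
    """Draw ``n`` log-normal weights with arithmetic mean ``scale*base_mean``.

    ``cv`` is the coefficient of variation of the distribution; ``cv = 0``
    degenerates to all weights exactly equal to the mean.
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if n < 0:
        raise ValueError("n must be nonnegative")
    mean = scale * base_mean
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _sample_pairs(rng, n_pre, n_post, p, forbid_self):
    """Ordered (pre, post) pairs, each kept independently with prob p."""
    mask = rng.random((n_pre, n_post)) < p
    if forbid_self:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


def build_network(spec: ConnectivitySpec) -> NetworkGraph:
    """Sample the full graph reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    readout_i = np.arange(spec.n_readout, dtype=np.int64)
    readout_e = np.arange(spec.n_readout, dtype=np.int64)

    chem = {}
    # I -> I
    pre, post = _sample_pairs(rng, spec.n_i, spec.n_i, spec.p_ii,
                              forbid_self=True)
    w = np.full(len(pre), float(spec.ii_weight))
    d = rng.uniform(*spec.delay_range, size=len(pre))
    chem["II"] = {"pre": pre, "post": post, "weight": w, "delay": d}

    # I -> E
    pre, post = _sample_pairs(rng, spec.n_i, spec.n_e, spec.p_ie,
                              forbid_self=False)
    w = sample_lognormal_weights(len(pre), spec.ie_base_mean,
                                 spec.ie_weight_mean_scale, rng,
                                 cv=spec.ie_weight_cv)
    d = rng.uniform(*spec.delay_range, size=len(pre))
    chem["IE"] = {"pre": pre, "post": post, "weight": w, "delay": d}

    # E -> I
    pre, post = _sample_pairs(rng, spec.n_e, spec.n_i, spec.p_ei,
                              forbid_self=False)
    if spec.ei_interpretation == "per_connection":
        w_ei = float(spec.ei_gmax)
    elif spec.ei_interpretation == "total":
        w_ei = float(spec.ei_gmax) / (spec.p_ei * spec.n_e)
    else:
        w_ei = float(spec.ei_gmax) / spec.ei_coincident
    if w_ei > 0 and spec.ei_weight_cv > 0:
        w = sample_lognormal_weights(len(pre), w_ei, 1.0, rng,
                                     cv=spec.ei_weight_cv)
    else:
        w = np.full(len(pre), w_ei)
    d = rng.uniform(*spec.delay_range, size=len(pre))
    chem["EI"] = {"pre": pre, "post": post, "weight": w, "delay": d}

    # gap junctions on unordered I pairs
    a, b = np.triu_indices(spec.n_i, k=1)
    keep = rng.random(len(a)) < spec.p_gap
    if not spec.readout_gap:
        keep &= ~np.isin(a, readout_i) & ~np.isin(b, readout_i)
    gap_a, gap_b = a[keep].astype(np.int64), b[keep].astype(np.int64)
    gap_g = np.full(len(gap_a), float(spec.gap_g))

    return NetworkGraph(n_i=spec.n_i, n_e=spec.n_e, chem=chem,
                        gap_a=gap_a, gap_b=gap_b, gap_g=gap_g,
                        readout_i=readout_i, readout_e=readout_e, spec=spec)
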