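"""Hourglass network of interconnected binding neurons.

Instead of a membrane potential, each neuron ``i`` carries the remaining
time to fire ``X_i(t)``, which decays linearly at unit rate.  When ``X_i``
reaches zero the neuron fires and its hourglass is refilled with the
(expected or sampled) interspike interval ``U_i`` of its own binding-neuron
dynamics, minus the elapsed step; every neighbour ``j`` inhibited by ``i``
gains ``w_ij`` (its firing is delayed) and every excited neighbour loses
``w_ij``, floored at zero:

    X_j(t + dt) = U_i - dt                    if j = i fires,
                  X_j(t) + w_ij - dt          if j in I_i,
                  max{0, X_j(t) - w_ij - dt}  if j in E_i.

The reference experiment is a 10 x 10 grid with purely inhibitory lateral
(4-neighbour) coupling, each neuron refilled with the mean ISI of an
exponential(lambda)-input, deterministic-lifetime binding neuron; neurons
are then classified by spike count as silent (<= 5), medium (6-200) or
high (> 200).

Several neurons may hit zero within one step; they are processed in
row-major index order, so an inhibitory increment from an earlier firer can
lift a later neuron off zero before it is tested.  All quantities share one
abstract time unit; weights and step sizes are conveniently expressed in
multiples of the refill mean E(T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .dist_models import as_rng
from .isi_analytics import BindingNeuronSpec, isi_mean
from . import binding_sim

__all__ = [
    "RefillSource",
    "ConstantRefill",
    "NeuronRefill",
    "GridSpec",
    "NetworkTopology",
    "NetworkState",
    "ActivityMap",
    "RunResult",
    "build_grid",
    "refill",
    "step",
    "run",
    "classify_activity",
    "silent_census",
    "grid_experiment",
]

ACTIVITY_THRESHOLDS = (5, 200)  # silent <= 5 < medium <= 200 < high


class RefillSource:
    """Interface: a per-neuron source of interspike intervals."""

    mean_interval: float

    def sample_interval(self, rng: np.random.Generator) -> float:
        raise NotImplementedError


@dataclass
class ConstantRefill(RefillSource):
    """Degenerate ISI law: every interval equals ``value``."""

    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("refill value must be positive")
        self.mean_interval = float(self.value)

    def sample_interval(self, rng) -> float:
        return float(self.value)


@dataclass
class NeuronRefill(RefillSource):
    """Refill drawn from the ISI law of a binding-neuron spec."""

    spec: BindingNeuronSpec

    def __post_init__(self):
        self.mean_interval = isi_mean(self.spec)
        if not math.isfinite(self.mean_interval):
            raise ValueError("non-finite mean ISI: the neuron never fires")

    def sample_interval(self, rng) -> float:
        rng_z, rng_tau = rng, rng
        return binding_sim._store_interval(self.spec, rng_z, rng_tau)[0]


@dataclass
class GridSpec:
    """Rectangular grid with homogeneous lateral 4-neighbour coupling."""

    rows: int
    cols: int
    connection_kind: str = "inhibitory"
    weight: Union[float, Callable[[float], float]] = 0.0
    refill: Optional[RefillSource] = None

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.connection_kind not in ("inhibitory", "excitatory"):
            raise ValueError("connection_kind must be inhibitory or excitatory")
        if not callable(self.weight) and self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass
class NetworkTopology:
    """Directed coupling structure plus per-neuron refill sources.

    ``inhibitory[i]`` / ``excitatory[i]`` hold the target index sets I_i and
    E_i of neuron ``i``; ``w_inh[i]`` / ``w_exc[i]`` the parallel weights.
    """

    n: int
    inhibitory: List[np.ndarray]
    excitatory: List[np.ndarray]
    w_inh: List[np.ndarray]
    w_exc: List[np.ndarray]
    refill: List[RefillSource]
    grid: Optional[GridSpec] = None

    def __post_init__(self):
        if len(self.refill) != self.n:
            raise ValueError("one refill source per neuron required")
        for i in range(self.n):
            ii, ei = set(self.inhibitory[i].tolist()), set(self.excitatory[i].tolist())
            if ii & ei:
                raise ValueError(f"neuron {i}: I_i and E_i must be disjoint")
            if i in ii or i in ei:
                raise ValueError(f"neuron {i}: self-connections are not allowed")
            for tgt in (self.inhibitory[i], self.excitatory[i]):
                if tgt.size and (tgt.min() < 0 or tgt.max() >= self.n):
                    raise ValueError(f"neuron {i}: target index out of range")
            if (np.any(self.w_inh[i] < 0) or np.any(self.w_exc[i] < 0)):
                raise ValueError(f"neuron {i}: weights must be nonnegative")


@dataclass
class NetworkState:
    """Mutable simulation state: clock, remaining times, counters, rng."""

    t: float
    X: np.ndarray
    spike_counts: np.ndarray
    rng: np.random.Generator


@dataclass
class ActivityMap:
    """Per-neuron activity labels, optionally laid out on a grid."""

    labels: np.ndarray  # array of {"silent", "medium", "high"}
    rows: Optional[int] = None
    cols: Optional[int] = None

    def as_grid(self) -> np.ndarray:
        if self.rows is None or self.cols is None:
            raise ValueError("no grid layout attached")
        return self.labels.reshape(self.rows, self.cols)


@dataclass
class RunResult:
    spike_counts: np.ndarray
    state: NetworkState
    raster: Optional[List[tuple]] = None


def build_grid(spec: GridSpec) -> NetworkTopology:
    """4-neighbour lateral topology on a rows x cols grid.

    Membership is symmetric for a constant weight; border neurons simply
    have fewer neighbours.  A callable weight receives the Euclidean grid
    distance (1.0 for lateral neighbours).
    """
    n = spec.rows * spec.cols
    wfun = spec.weight if callable(spec.weight) else (lambda d: spec.weight)
    inh = [[] for _ in range(n)]
    exc = [[] for _ in range(n)]
    w_i = [[] for _ in range(n)]
    w_e = [[] for _ in range(n)]
    for r in range(spec.rows):
        for c in range(spec.cols):
            i = r * spec.cols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < spec.rows and 0 <= cc < spec.cols:
                    j = rr * spec.cols + cc
                    w = float(wfun(1.0))
                    if spec.connection_kind == "inhibitory":
                        inh[i].append(j)
                        w_i[i].append(w)
                    else:
                        exc[i].append(j)
                        w_e[i].append(w)
    refill_src = spec.refill if spec.refill is not None else ConstantRefill(1.0)
    return NetworkTopology(
        n=n,
        inhibitory=[np.array(x, dtype=int) for x in inh],
        excitatory=[np.array(x, dtype=int) for x in exc],
        w_inh=[np.array(x) for x in w_i],
        w_exc=[np.array(x) for x in w_e],
        refill=[refill_src] * n,
        grid=spec,
    )


def refill(state: NetworkState, i: int, policy: str,
           rng: Optional[np.random.Generator] = None) -> float:
    """Refill amount U_i for neuron ``i`` that just fired.

    ``mean`` uses E(T) of the neuron's ISI law; ``sampled`` draws a fresh
    interval.  The caller applies the ``U_i - dt`` step convention.
    """
    if not hasattr(state, "_refill_sources"):
        raise ValueError("state was not produced by init_state/run")
    source = state._refill_sources[i]
    return _refill_value(source, policy, rng if rng is not None else state.rng)


def _refill_value(source: RefillSource, policy: str, rng) -> float:
    if policy == "mean":
        return source.mean_interval
    if policy == "sampled":
        return source.sample_interval(rng)
    raise ValueError("policy must be 'mean' or 'sampled'")


def init_state(topology: NetworkTopology, seed, refill_policy: str = "mean",
               stagger: bool = False) -> NetworkState:
    """Initial state: X_i(0) from the refill policy, plus optional i.i.d.
    uniform(0, E(T_i)) phase jitter to break the symmetry of identical
    starts."""
    rng = as_rng(seed)
    X = np.array([_refill_value(src, refill_policy, rng)
                  for src in topology.refill], dtype=float)
    if stagger:
        means = np.array([src.mean_interval for src in topology.refill])
        X = X + rng.uniform(0.0, means)
    state = NetworkState(t=0.0, X=X,
                         spike_counts=np.zeros(topology.n, dtype=np.int64),
                         rng=rng)
    state._refill_sources = topology.refill
    return state


def step(state: NetworkState, topology: NetworkTopology, dt: float,
         refill_policy: str = "mean") -> List[int]:
    """Advance one time step of size ``dt``; returns fired neurons in
    processing order.

    All X_i decrease by dt; any neuron at (or below, within tolerance) zero
    fires: its own hourglass is refilled to U_i - dt, inhibited targets gain
    w_ij and excited targets lose w_ij with a floor at zero.

    Eligibility is fixed right after the decrement: a neuron pushed onto
    zero by an excitatory kick within this step fires at the next step's
    test, while an inhibitory increment from an earlier firer can still lift
    an eligible neuron off zero before it is processed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tol = dt * 1e-6
    X = state.X
    X -= dt
    fired: List[int] = []
    if X.min() <= tol:
        for i in np.flatnonzero(X <= tol):
            i = int(i)
            if X[i] <= tol:
                fired.append(i)
                state.spike_counts[i] += 1
                u = _refill_value(topology.refill[i], refill_policy, state.rng)
                X[i] = u - dt
                tgt = topology.inhibitory[i]
                if tgt.size:
                    X[tgt] += topology.w_inh[i]
                tgt = topology.excitatory[i]
                if tgt.size:
                    X[tgt] = np.maximum(0.0, X[tgt] - topology.w_exc[i])
    np.maximum(X, 0.0, out=X)
    state.t += dt
    return fired


def run(topology: NetworkTopology, horizon: float, dt: float, seed,
        refill_policy: str = "mean", stagger: bool = False,
        record_raster: bool = False) -> RunResult:
    """Run ``ceil(horizon/dt)`` steps from a freshly initialized state."""
    if horizon <= 0 or dt <= 0:
        raise ValueError("horizon and dt must be positive")
    means = [src.mean_interval for src in topology.refill]
    if dt >= min(means):
        import warnings
        warnings.warn("dt is not small relative to the refill times; "
                      "dynamics will be undersampled", stacklevel=2)
    state = init_state(topology, seed, refill_policy, stagger)
    raster: Optional[List[tuple]] = [] if record_raster else None
    n_steps = int(math.ceil(horizon / dt))
    for _ in range(n_steps):
        fired = step(state, topology, dt, refill_policy)
        if raster is not None:
            for i in fired:
                raster.append((state.t, i))
    return RunResult(spike_counts=state.spike_counts.copy(), state=state,
                     raster=raster)


def classify_activity(spike_counts,
                      thresholds=ACTIVITY_THRESHOLDS,
                      rows: Optional[int] = None,
                      cols: Optional[int] = None) -> ActivityMap:
    """Label neurons silent (<= thresholds[0]), medium (<= thresholds[1])
    or high (above)."""
    counts = np.asarray(spike_counts)
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    lo, hi = thresholds
    labels = np.where(counts <= lo, "silent",
                      np.where(counts <= hi, "medium", "high"))
    return ActivityMap(labels=labels, rows=rows, cols=cols)


def silent_census(amap: ActivityMap, grid: Optional[GridSpec] = None) -> dict:
    """Count silent neurons in total, strictly interior, and on the border."""
    if grid is not None:
        rows, cols = grid.rows, grid.cols
    elif amap.rows is not None:
        rows, cols = amap.rows, amap.cols
    else:
        raise ValueError("grid layout required for a census")
    g = amap.labels.reshape(rows, cols) == "silent"
    total = int(g.sum())
    interior = int(g[1:-1, 1:-1].sum()) if rows > 2 and cols > 2 else 0
    return {"n_silent": total,
            "n_silent_interior": interior,
            "n_silent_border": total - interior}


def interior_border_means(spike_counts, rows: int, cols: int):
    """Mean spike count of the strict interior block and the border ring."""
    g = np.asarray(spike_counts, dtype=float).reshape(rows, cols)
    mask = np.zeros((rows, cols), dtype=bool)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    border = g[mask].mean()
    interior = g[~mask].mean() if (~mask).any() else float("nan")
    return interior, border


def grid_experiment(rows: int = 10, cols: int = 10, lam: float = 15.0,
                    tau: float = 1.0, w_rel: float = 4.0,
                    horizon_rel: float = 300.0, dt_rel: float = 0.05,
                    seed=0, refill_policy: str = "mean",
                    stagger: bool = True) -> RunResult:
    """Reference inhibitory-grid experiment.

    Each neuron is an exponential(lam)-input, deterministic-lifetime(tau)
    binding neuron; the lateral inhibitory weight, step size and horizon are
    given in multiples of the mean ISI E(T) so the experiment is
    well-defined in one abstract time unit.  Defaults: dt = E(T)/20 and a
    horizon of 300 E(T), long enough that an uncoupled neuron lands in the
    high-activity class (~300 spikes).
    """
    from .dist_models import InterArrivalModel, LifetimeModel

    spec = BindingNeuronSpec(InterArrivalModel.exponential(lam),
                             LifetimeModel.deterministic(tau))
    src = NeuronRefill(spec)
    e_t = src.mean_interval
    gspec = GridSpec(rows=rows, cols=cols, connection_kind="inhibitory",
                     weight=w_rel * e_t, refill=src)
    topo = build_grid(gspec)
    return run(topo, horizon=horizon_rel * e_t, dt=dt_rel * e_t, seed=seed,
               refill_policy=refill_policy, stagger=stagger)
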