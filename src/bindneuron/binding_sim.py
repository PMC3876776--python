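"""Event-driven Monte-Carlo simulation of a binding neuron.

Ground-truth oracle for the analytic ISI routes and the only route for
general threshold ``K``.  Two independent algorithms are provided:

* a general *store* algorithm that keeps the full set of stored impulses
  with their expiry times (any ``K``, with or without feedback), and
* a vectorized *fast* path for the analytic regime ``K = 2`` with feedback,
  built directly on the geometric-compound decomposition of the interval
  (each round is one fresh (Z, tau) pair; the round fires iff Z < tau).

The two paths consume randomness differently, so they agree statistically,
not draw-for-draw; tests use them as mutual oracles.

Conventions: a simultaneous arrival-and-expiry (probability zero for
continuous laws) is resolved by processing the expiry first, i.e. an impulse
is stored for exactly its lifetime and then lost.  A cap of 1e7 input events
per requested interval guards against never-firing configurations (q = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dist_models import as_rng
from .isi_analytics import BindingNeuronSpec

__all__ = ["SpikeTrain", "simulate_isi", "simulate_train", "summarize"]

MAX_EVENTS_PER_INTERVAL = 10_000_000
_BLOCK = 1 << 16


@dataclass(frozen=True)
class SpikeTrain:
    """Realized spike times with per-interval wasted-impulse counts.

    ``spike_times`` excludes the time-origin spike that starts the process;
    with ``n`` completed intervals, ``spike_times[k] = sum(isis[:k+1])``.
    ``wasted_counts[k]`` is the number of impulses in interval ``k`` that
    expired without contributing to the firing (the geometric count with
    success probability q in the K = 2 feedback regime).
    """

    spike_times: np.ndarray
    isis: np.ndarray
    wasted_counts: np.ndarray
    seed: Optional[int]
    spec: BindingNeuronSpec

    def __post_init__(self):
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if np.any(self.isis <= 0) or np.any(self.wasted_counts < 0):
            raise ValueError("invalid interval data")


def _spawn_rngs(seed):
    ss = np.random.SeedSequence(seed)
    kz, kt = ss.spawn(2)
    return np.random.default_rng(kz), np.random.default_rng(kt)


def _fast_intervals(spec, n, rng_z, rng_tau):
    """Vectorized K = 2 feedback path: block draws of (Z, tau) rounds."""
    z_model, lt_model = spec.interarrival, spec.lifetime
    isis = np.empty(n)
    wasted = np.empty(n, dtype=np.int64)
    count = 0
    t_acc = 0.0
    w_acc = 0
    block = int(min(_BLOCK, max(1024, 2 * n)))
    while count < n:
        z = z_model.sample(block, rng_z)
        tau = lt_model.sample(block, rng_tau)
        hit = z < tau  # expiry processed before arrival
        idx = np.flatnonzero(hit)
        cum = np.cumsum(z)
        if idx.size == 0:
            t_acc += cum[-1]
            w_acc += block
            if w_acc > MAX_EVENTS_PER_INTERVAL:
                raise RuntimeError(
                    "no firing after 1e7 input events: configuration with "
                    "q = 0 (the neuron can never reach threshold)")
            continue
        ends = cum[idx]
        isis_blk = np.diff(ends, prepend=0.0)
        isis_blk[0] += t_acc
        wasted_blk = np.diff(idx, prepend=-1) - 1
        wasted_blk[0] += w_acc
        if wasted_blk.max() > MAX_EVENTS_PER_INTERVAL:
            raise RuntimeError("interval exceeded the 1e7-event cap")
        take = min(n - count, idx.size)
        isis[count:count + take] = isis_blk[:take]
        wasted[count:count + take] = wasted_blk[:take]
        count += take
        if take == idx.size:
            t_acc = cum[-1] - ends[-1]
            w_acc = int(block - 1 - idx[-1])
    return isis, wasted


def _store_interval(spec, rng_z, rng_tau):
    """One interval with the general impulse store; returns (isi, wasted)."""
    k = spec.threshold
    t = 0.0
    expiries = []
    if spec.feedback:
        expiries.append(float(spec.lifetime.sample(1, rng_tau)[0]))
    wasted = 0
    events = 0
    while True:
        t += float(spec.interarrival.sample(1, rng_z)[0])
        events += 1
        if events > MAX_EVENTS_PER_INTERVAL:
            raise RuntimeError(
                "no firing after 1e7 input events: configuration with q = 0")
        live = [e for e in expiries if e > t]  # expiry before arrival
        wasted += len(expiries) - len(live)
        expiries = live
        if len(expiries) + 1 >= k:
            return t, wasted
        expiries.append(t + float(spec.lifetime.sample(1, rng_tau)[0]))


def simulate_isi(spec: BindingNeuronSpec, n_intervals: int, seed,
                 method: str = "auto") -> SpikeTrain:
    """Simulate ``n_intervals`` interspike intervals.

    ``method`` is ``"fast"`` (K = 2 with feedback only), ``"store"`` (general
    algorithm) or ``"auto"``.  Identical ``(spec, n_intervals, seed, method)``
    give byte-identical output.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    rng_z, rng_tau = _spawn_rngs(seed)
    fast_ok = spec.threshold == 2 and spec.feedback
    if method == "auto":
        method = "fast" if fast_ok else "store"
    if method == "fast":
        if not fast_ok:
            raise ValueError("fast path requires K = 2 with feedback")
        isis, wasted = _fast_intervals(spec, n_intervals, rng_z, rng_tau)
    elif method == "store":
        pairs = [_store_interval(spec, rng_z, rng_tau)
                 for _ in range(n_intervals)]
        isis = np.array([p[0] for p in pairs])
        wasted = np.array([p[1] for p in pairs], dtype=np.int64)
    else:
        raise ValueError("method must be 'auto', 'fast' or 'store'")
    return SpikeTrain(spike_times=np.cumsum(isis), isis=isis,
                      wasted_counts=wasted,
                      seed=seed if np.isscalar(seed) else None, spec=spec)


def simulate_train(spec: BindingNeuronSpec, horizon: float, seed,
                   method: str = "auto") -> SpikeTrain:
    """Simulate all spikes in ``(0, horizon]``; may return an empty train."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng_z, rng_tau = _spawn_rngs(seed)
    fast_ok = spec.threshold == 2 and spec.feedback
    if method == "auto":
        method = "fast" if fast_ok else "store"
    isis = []
    wasted = []
    t = 0.0
    while True:
        if method == "fast":
            blk_i, blk_w = _fast_intervals(spec, 256, rng_z, rng_tau)
        else:
            pairs = [_store_interval(spec, rng_z, rng_tau) for _ in range(64)]
            blk_i = np.array([p[0] for p in pairs])
            blk_w = np.array([p[1] for p in pairs], dtype=np.int64)
        for dt_i, w_i in zip(blk_i, blk_w):
            t += dt_i
            if t > horizon:
                st = np.cumsum(np.asarray(isis))
                return SpikeTrain(
                    spike_times=st, isis=np.asarray(isis),
                    wasted_counts=np.asarray(wasted, dtype=np.int64),
                    seed=seed if np.isscalar(seed) else None, spec=spec)
            isis.append(dt_i)
            wasted.append(w_i)


def summarize(train: SpikeTrain) -> dict:
    """Sample ISI statistics with standard errors.

    SE of the mean is s/sqrt(n); SE of the CV uses the delta method with
    empirical third and fourth central moments.
    """
    x = np.asarray(train.isis, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two intervals to summarize")
    m = x.mean()
    v = x.var(ddof=1)
    s = math.sqrt(v)
    cv = s / m
    se_mean = s / math.sqrt(n)
    if v > 0:
        d = x - m
        mu3 = np.mean(d**3)
        mu4 = np.mean(d**4)
        # gradient of cv = sqrt(v)/m w.r.t. (m, v)
        g_m = -s / m**2
        g_v = 1.0 / (2.0 * m * s)
        var_cv = (g_m**2 * v / n
                  + g_v**2 * max(mu4 - v * v, 0.0) / n
                  + 2.0 * g_m * g_v * mu3 / n)
        se_cv = math.sqrt(max(var_cv, 0.0))
    else:
        se_cv = 0.0
    return {"n": int(n), "mean": m, "variance": v, "cv": cv,
            "se_mean": se_mean, "se_cv": se_cv}
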