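"""Input laws of the binding-neuron model.

A binding neuron is driven by a renewal stream whose inter-arrival times
``Z`` are i.i.d. with density ``f_Z``; every stored impulse survives for a
lifetime drawn from an independent law ``tau``.  This module represents the
two laws with evaluable densities, distribution/survival functions, raw and
truncated moments, and seeded samplers.

Built-in kinds wrap frozen :mod:`scipy.stats` distributions.  Custom laws
must supply density, CDF, survival and sampler jointly; no numerical
differentiation of a CDF is attempted.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "InterArrivalModel",
    "LifetimeModel",
    "pdf_at",
    "moment",
    "sample",
    "truncated_mean_above",
]

# Quadrature policy for custom laws: absolute 1e-10, relative 1e-8, upper
# limit at the 1 - 1e-12 quantile.
_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-8, limit=200)
_TAIL_EPS = 1e-12


def _check_time(t):
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("time must be nonnegative")
    return arr


def as_rng(seed) -> np.random.Generator:
    """Coerce an integer seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _BaseModel:
    """Shared surface of the two input laws."""

    kind: str
    label: str

    def pdf(self, t):
        raise NotImplementedError

    def cdf(self, t):
        raise NotImplementedError

    def survival(self, t):
        raise NotImplementedError

    def sample(self, n: int, seed) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v!r}" for k, v in self.params().items())
        return f"{type(self).__name__}({inner})"


class InterArrivalModel(_BaseModel):
    """Renewal law of the time ``Z`` between successive input impulses.

    Use the constructors :meth:`exponential`, :meth:`uniform` or
    :meth:`custom`; the plain ``__init__`` is internal.
    """

    def __init__(self, kind, *, rate=None, a=None, b=None, density=None,
                 cdf=None, survival=None, sampler=None, label=None):
        self.kind = kind
        self.rate = rate
        self.a = a
        self.b = b
        self._density = density
        self._cdf = cdf
        self._survival = survival
        self._sampler = sampler
        if kind == "exponential":
            if not (rate is not None and rate > 0):
                raise ValueError("exponential interarrival law needs rate > 0")
            self._dist = stats.expon(scale=1.0 / rate)
        elif kind == "uniform":
            if a is None or b is None or not (0 <= a < b):
                raise ValueError("uniform interarrival law needs 0 <= a < b")
            self._dist = stats.uniform(loc=a, scale=b - a)
        elif kind == "custom":
            if not all(callable(f) for f in (density, cdf, survival, sampler)):
                raise ValueError(
                    "custom law must supply density, cdf, survival and sampler jointly")
            self._dist = None
        else:
            raise ValueError(f"unknown interarrival kind {kind!r}")
        self.label = label or kind

    # -- constructors -----------------------------------------------------
    @classmethod
    def exponential(cls, rate: float) -> "InterArrivalModel":
        """Poisson input stream: ``f_Z(t) = rate * exp(-rate * t)``."""
        return cls("exponential", rate=float(rate))

    @classmethod
    def uniform(cls, a: float, b: float) -> "InterArrivalModel":
        """Uniform inter-arrival times on ``[a, b]``, ``0 <= a < b``."""
        return cls("uniform", a=float(a), b=float(b))

    @classmethod
    def custom(cls, *, density: Callable, cdf: Callable, survival: Callable,
               sampler: Callable, label: str = "custom") -> "InterArrivalModel":
        """User-supplied law; ``sampler(n, rng)`` must honour the given rng."""
        return cls("custom", density=density, cdf=cdf, survival=survival,
                   sampler=sampler, label=label)

    # -- evaluation -------------------------------------------------------
    def pdf(self, t):
        t = _check_time(t)
        if self._dist is not None:
            return self._dist.pdf(t)
        return np.asarray(self._density(t), dtype=float)

    def cdf(self, t):
        t = _check_time(t)
        if self._dist is not None:
            return self._dist.cdf(t)
        return np.asarray(self._cdf(t), dtype=float)

    def survival(self, t):
        t = _check_time(t)
        if self._dist is not None:
            return self._dist.sf(t)
        return np.asarray(self._survival(t), dtype=float)

    def ppf(self, u):
        if self._dist is not None:
            return self._dist.ppf(u)
        u = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.empty_like(u)
        hi = 1.0
        while float(self._cdf(hi)) < u.max():
            hi *= 2.0
            if hi > 1e18:  # pragma: no cover - pathological custom law
                raise RuntimeError("quantile search failed for custom law")
        for i, ui in enumerate(u):
            out[i] = optimize.brentq(lambda x: float(self._cdf(x)) - ui, 0.0, hi)
        return out if out.size > 1 else float(out[0])

    def upper_limit(self, eps: float = _TAIL_EPS) -> float:
        """Integration cut-off: the ``1 - eps`` quantile of the law."""
        return float(self.ppf(1.0 - eps))

    def moment(self, k: int) -> float:
        """Raw moment E(Z^k), k in {1, 2}."""
        if k not in (1, 2):
            raise ValueError("only raw moments of order 1 and 2 are supported")
        if self.kind == "exponential":
            return (1.0 / self.rate) if k == 1 else 2.0 / self.rate**2
        if self.kind == "uniform":
            a, b = self.a, self.b
            if k == 1:
                return (a + b) / 2.0
            return (a * a + a * b + b * b) / 3.0
        val, _ = integrate.quad(lambda t: t**k * float(self._density(t)),
                                0.0, self.upper_limit(), **_QUAD_KW)
        return val

    @property
    def mean(self) -> float:
        return self.moment(1)

    def sample(self, n: int, seed) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = as_rng(seed)
        if self.kind == "exponential":
            return rng.exponential(1.0 / self.rate, size=n)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=n)
        return np.asarray(self._sampler(n, rng), dtype=float)

    def truncated_mean_above(self, c: float) -> float:
        """Conditional mean E(Z | Z > c)."""
        c = float(c)
        if c < 0:
            raise ValueError("threshold must be nonnegative")
        tail = float(self.survival(c))
        if tail <= 0.0:
            raise ValueError("P(Z > c) = 0: conditional mean undefined")
        if self.kind == "exponential":
            # memorylessness
            return c + 1.0 / self.rate
        if self.kind == "uniform":
            lo = max(self.a, c)
            return (lo + self.b) / 2.0
        num, _ = integrate.quad(lambda t: t * float(self._density(t)),
                                c, self.upper_limit(), **_QUAD_KW)
        return num / tail

    def params(self) -> dict:
        if self.kind == "exponential":
            return {"kind": self.kind, "rate": self.rate}
        if self.kind == "uniform":
            return {"kind": self.kind, "a": self.a, "b": self.b}
        return {"kind": self.kind, "label": self.label}


class LifetimeModel(_BaseModel):
    """Law of the impulse lifetime ``tau``.

    The deterministic kind is the step CDF ``G(t) = 1{t >= tau}`` of the
    original fixed-lifetime model; the exponential kind is the mass-service
    generalization with ``survival(t) = exp(-mu t)``.
    """

    def __init__(self, kind, *, tau=None, rate=None, density=None, cdf=None,
                 survival=None, sampler=None, label=None):
        self.kind = kind
        self.tau = tau
        self.rate = rate
        self._density = density
        self._cdf = cdf
        self._survival = survival
        self._sampler = sampler
        if kind == "deterministic":
            if not (tau is not None and tau > 0):
                raise ValueError("deterministic lifetime needs tau > 0")
        elif kind == "exponential":
            if not (rate is not None and rate > 0):
                raise ValueError("exponential lifetime needs rate > 0")
        elif kind == "custom":
            if not all(callable(f) for f in (density, cdf, survival, sampler)):
                raise ValueError(
                    "custom law must supply density, cdf, survival and sampler jointly")
        else:
            raise ValueError(f"unknown lifetime kind {kind!r}")
        self.label = label or kind

    @classmethod
    def deterministic(cls, tau: float) -> "LifetimeModel":
        return cls("deterministic", tau=float(tau))

    @classmethod
    def exponential(cls, rate: float) -> "LifetimeModel":
        return cls("exponential", rate=float(rate))

    @classmethod
    def custom(cls, *, density, cdf, survival, sampler,
               label: str = "custom") -> "LifetimeModel":
        return cls("custom", density=density, cdf=cdf, survival=survival,
                   sampler=sampler, label=label)

    def pdf(self, t):
        t = _check_time(t)
        if self.kind == "deterministic":
            # unit point mass at tau: no density; report the singular point
            return np.where(t == self.tau, np.inf, 0.0)
        if self.kind == "exponential":
            return self.rate * np.exp(-self.rate * t)
        return np.asarray(self._density(t), dtype=float)

    def cdf(self, t):
        t = _check_time(t)
        if self.kind == "deterministic":
            # right-continuous step: G(tau) = 1
            return (t >= self.tau).astype(float)
        if self.kind == "exponential":
            return -np.expm1(-self.rate * t)
        return np.asarray(self._cdf(t), dtype=float)

    def survival(self, t):
        t = _check_time(t)
        if self.kind == "deterministic":
            return (t < self.tau).astype(float)
        if self.kind == "exponential":
            return np.exp(-self.rate * t)
        return np.asarray(self._survival(t), dtype=float)

    @property
    def mean(self) -> float:
        if self.kind == "deterministic":
            return self.tau
        if self.kind == "exponential":
            return 1.0 / self.rate
        val, _ = integrate.quad(lambda t: t * float(self._density(t)),
                                0.0, np.inf, **_QUAD_KW)
        return val

    def sample(self, n: int, seed) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = as_rng(seed)
        if self.kind == "deterministic":
            return np.full(n, self.tau, dtype=float)
        if self.kind == "exponential":
            return rng.exponential(1.0 / self.rate, size=n)
        return np.asarray(self._sampler(n, rng), dtype=float)

    def params(self) -> dict:
        if self.kind == "deterministic":
            return {"kind": self.kind, "tau": self.tau}
        if self.kind == "exponential":
            return {"kind": self.kind, "rate": self.rate}
        return {"kind": self.kind, "label": self.label}


# -- module-level operation wrappers --------------------------------------

def pdf_at(model: _BaseModel, t):
    """Density of the law at time(s) ``t`` (0 outside the support)."""
    return model.pdf(t)


def moment(model: InterArrivalModel, k: int) -> float:
    """Raw moment E(Z^k) of an inter-arrival law, k in {1, 2}."""
    return model.moment(k)


def sample(model: _BaseModel, n: int, seed) -> np.ndarray:
    """``n`` i.i.d. draws; identical (seed, n) give identical output."""
    return model.sample(n, seed)


def truncated_mean_above(model: InterArrivalModel, c: float) -> float:
    """Conditional mean E(Z | Z > c); raises when P(Z > c) = 0."""
    return model.truncated_mean_above(c)
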