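"""Voltage-dependent rate laws for channel gating transitions.

Every transition in a gating scheme carries a rate law mapping membrane
voltage V (mV) to a transition rate (1/ms).  Three closed-form families
cover the model: a simple exponential ``k*exp(V/n)``, a saturating sigmoid
``g/(1+exp(-(V+a)/f))``, and scaled copies of another law.  A fourth,
:class:`BalanceRateLaw`, has no parameters of its own: its value is derived
at evaluation time from microscopic reversibility of a reaction cycle (see
:mod:`navmarkov.scheme`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateLaw",
    "ExpRateLaw",
    "SigmoidRateLaw",
    "ScaledRateLaw",
    "BalanceRateLaw",
    "eval_rate",
]


def _check_voltage(V):
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError(f"membrane voltage must be finite, got {V!r}")
    return V


class RateLaw:
    """Base class: a callable V (mV) -> rate (1/ms), strictly positive."""

    def __call__(self, V):
        V = _check_voltage(V)
        r = self._rate(V)
        return float(r) if np.isscalar(V) or V.ndim == 0 else r

    def _rate(self, V):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class ExpRateLaw(RateLaw):
    """``rate(V) = k * exp(V / n)``.

    ``k`` is the pre-exponential factor (1/ms) and ``n`` the exponential
    voltage factor (mV); negative ``n`` gives rates that grow with
    hyperpolarization.  A voltage-independent rate is expressed by
    ``constant=True`` (rate = k for every V) rather than by a huge ``n``,
    which avoids spurious exp() evaluation.
    """

    k: float
    n: float = field(default=float("inf"))
    constant: bool = False

    def __post_init__(self):
        if not (self.k > 0):
            raise ValueError(f"pre-exponential factor k must be > 0, got {self.k}")
        if not self.constant:
            if self.n == 0 or not math.isfinite(self.n):
                raise ValueError(
                    "exponential factor n must be finite and nonzero; "
                    "use constant=True for a voltage-independent rate"
                )

    def _rate(self, V):
        if self.constant:
            return np.broadcast_to(np.float64(self.k), np.shape(V)).copy()
        return self.k * np.exp(V / self.n)


@dataclass(frozen=True)
class SigmoidRateLaw(RateLaw):
    """``rate(V) = g / (1 + exp(-(V + a) / f))``.

    Saturates at ``g`` (1/ms) for strong depolarization, vanishes for
    strong hyperpolarization, and equals ``g/2`` exactly at ``V = -a``.
    """

    g: float
    a: float
    f: float

    def __post_init__(self):
        if not (self.g > 0):
            raise ValueError(f"maximal rate g must be > 0, got {self.g}")
        if not (self.f > 0):
            raise ValueError(f"slope factor f must be > 0, got {self.f}")

    def _rate(self, V):
        return self.g / (1.0 + np.exp(-(V + self.a) / self.f))


@dataclass(frozen=True)
class ScaledRateLaw(RateLaw):
    """``rate(V) = c * base(V)`` for a dimensionless multiplier ``c > 0``."""

    base: RateLaw
    c: float

    def __post_init__(self):
        if not (self.c > 0):
            raise ValueError(f"scale factor c must be > 0, got {self.c}")

    def _rate(self, V):
        base = self.base(V)
        return self.c * np.asarray(base, dtype=float)


@dataclass(frozen=True)
class BalanceRateLaw(RateLaw):
    """Rate derived from microscopic reversibility of a closed cycle.

    The cycle is an ordered tuple of state names ``(s0, s1, ..., s0)``
    traversed in one orientation.  The owning transition must be one of the
    cycle's edges; its rate is whatever value makes the product of rates in
    the cycle orientation equal the product against it at every voltage.
    The law cannot be evaluated standalone — the scheme resolves it against
    its sibling transitions (:meth:`KineticScheme.resolve_balance`).
    """

    cycle: tuple[str, ...]

    def __post_init__(self):
        if len(self.cycle) < 4 or self.cycle[0] != self.cycle[-1]:
            raise ValueError(
                "cycle must be a closed walk (first state repeated last) "
                f"with at least 3 distinct states, got {self.cycle!r}"
            )

    def _rate(self, V):
        raise RuntimeError(
            "a balance-derived rate can only be evaluated through its "
            "KineticScheme, which supplies the sibling cycle rates"
        )


def eval_rate(law: RateLaw, V):
    """Evaluate ``law`` at membrane voltage ``V`` (mV); returns 1/ms."""
    return law(V)
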