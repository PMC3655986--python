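"""Declarative gating schemes: states, transitions, generator matrices.

A :class:`KineticScheme` is a directed transition graph over named
conformational states, exactly one of which conducts.  Each transition
carries a :class:`LawSpec` — a *declarative* reference to a rate law and the
named parameters it draws from — so the same scheme can be evaluated under
any :class:`ModelParameters` set.  The scheme assembles the generator
(Q) matrix at any voltage, with off-diagonal entry ``Q[i, j]`` the i→j rate
and diagonals the negative row sums, governing ``dp/dt = p · Q``.

Rates declared with the ``balance`` law are not free parameters: they are
computed at evaluation time from microscopic reversibility of a declared
reaction cycle, so that the product of rates around the cycle equals the
product against it at every voltage.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .rates import BalanceRateLaw, ExpRateLaw, RateLaw, ScaledRateLaw, SigmoidRateLaw

__all__ = [
    "LawSpec",
    "Transition",
    "ModelParameters",
    "KineticScheme",
    "build_generator",
    "derive_reversibility_rate",
    "stationary_distribution",
]


@dataclass(frozen=True)
class LawSpec:
    """Declarative rate-law reference, bound to numbers via ModelParameters.

    kind:
      ``exp``      k·exp(V/n) from the (k, n) entry named ``param``
      ``sigmoid``  g/(1+exp(−(V+a)/f)) from the (g, a, f) entry ``param``
      ``scaled``   another entry's law multiplied by scalar entry ``by``
                   raised to ``power`` (e.g. row-to-row copies scaled by c)
      ``balance``  derived from microscopic reversibility of ``cycle``
      ``fixed``    a literal voltage-independent rate ``value`` (toys/tests)
    """

    kind: str
    param: str | None = None
    by: str | None = None
    power: int = 1
    cycle: tuple[str, ...] | None = None
    value: float | None = None

    def __post_init__(self):
        kinds = {"exp", "sigmoid", "scaled", "balance", "fixed"}
        if self.kind not in kinds:
            raise ValueError(f"unknown law kind {self.kind!r}; expected one of {sorted(kinds)}")
        if self.kind in {"exp", "sigmoid", "scaled"} and not self.param:
            raise ValueError(f"law kind {self.kind!r} requires a parameter name")
        if self.kind == "scaled" and not self.by:
            raise ValueError("scaled law requires the name of the scalar multiplier ('by')")
        if self.kind == "balance" and not self.cycle:
            raise ValueError("balance law requires a cycle (closed walk of state names)")
        if self.kind == "fixed" and self.value is None:
            raise ValueError("fixed law requires a literal rate value")
        if self.cycle is not None:
            object.__setattr__(self, "cycle", tuple(self.cycle))


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    law: LawSpec

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-transition {self.source!r} -> itself is not allowed")


class ModelParameters(Mapping):
    """Named parameter entries for a scheme's rate laws.

    Entries are either scalars (dimensionless multipliers such as ``c``),
    ``(k, n)`` mappings for exponential laws, or ``(g, a, f)`` mappings for
    sigmoid laws.  Pre-exponential factors and scalars must be positive;
    exponential voltage factors ``n`` may be negative.
    """

    def __init__(self, entries: Mapping):
        self._entries = {}
        for name, value in entries.items():
            if isinstance(value, Mapping):
                value = {k: float(v) for k, v in value.items()}
                keys = set(value)
                if keys == {"k", "n"} or keys == {"k"}:
                    if value["k"] <= 0:
                        raise ValueError(f"parameter {name}: k must be > 0, got {value['k']}")
                elif keys == {"g", "a", "f"}:
                    if value["g"] <= 0 or value["f"] <= 0:
                        raise ValueError(f"parameter {name}: g and f must be > 0")
                else:
                    raise ValueError(
                        f"parameter {name}: expected keys (k[, n]) or (g, a, f), got {sorted(keys)}"
                    )
            else:
                value = float(value)
                if value <= 0:
                    raise ValueError(f"scalar parameter {name} must be > 0, got {value}")
            self._entries[name] = value

    def __getitem__(self, name):
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def replace(self, **updates) -> "ModelParameters":
        """Return a copy with named entries replaced.

        Dotted names update one field of a mapping entry, e.g.
        ``replace(**{"alpha1.k": 10.0})``.
        """
        entries = {k: (dict(v) if isinstance(v, dict) else v) for k, v in self._entries.items()}
        for name, value in updates.items():
            if "." in name:
                base, fld = name.split(".", 1)
                entries[base][fld] = float(value)
            else:
                entries[name] = value
        return ModelParameters(entries)

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._entries, fh, sort_keys=False)

    def bind(self, spec: LawSpec) -> RateLaw:
        """Construct the numeric RateLaw a LawSpec refers to."""
        if spec.kind == "fixed":
            return ExpRateLaw(k=spec.value, constant=True)
        if spec.kind == "balance":
            return BalanceRateLaw(cycle=spec.cycle)
        entry = self._entries.get(spec.param)
        if entry is None:
            raise KeyError(f"scheme references parameter {spec.param!r}, absent from the set")
        if spec.kind == "sigmoid":
            return SigmoidRateLaw(**entry)
        if isinstance(entry, dict) and "g" in entry:
            base: RateLaw = SigmoidRateLaw(**entry)
        elif isinstance(entry, dict) and "n" in entry:
            base = ExpRateLaw(k=entry["k"], n=entry["n"])
        elif isinstance(entry, dict):
            base = ExpRateLaw(k=entry["k"], constant=True)
        else:
            raise ValueError(f"parameter {spec.param!r} is a scalar; cannot serve as a rate law")
        if spec.kind == "exp":
            return base
        scale = self._entries.get(spec.by)
        if scale is None:
            raise KeyError(f"scheme references scale parameter {spec.by!r}, absent from the set")
        if not np.isscalar(scale):
            raise ValueError(f"scale parameter {spec.by!r} must be a scalar")
        return ScaledRateLaw(base=base, c=float(scale) ** spec.power)


def _connected(states, edges) -> bool:
    if not states:
        return False
    adj = {s: set() for s in states}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, stack = {states[0]}, [states[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(states)


class KineticScheme:
    """A gating scheme: ordered states, one conducting state, transitions."""

    def __init__(self, states, conducting: str, transitions, name: str = "scheme"):
        self.name = name
        self.states = list(states)
        self.conducting = conducting
        self.transitions = list(transitions)
        self._index = {s: i for i, s in enumerate(self.states)}
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state names")
        if self.conducting not in self._index:
            raise ValueError(f"conducting state {self.conducting!r} not among states")
        seen = set()
        for tr in self.transitions:
            if tr.source not in self._index or tr.target not in self._index:
                raise ValueError(f"transition {tr.source}->{tr.target} references unknown state")
            key = (tr.source, tr.target)
            if key in seen:
                raise ValueError(f"duplicate transition {tr.source}->{tr.target}")
            seen.add(key)
        if not _connected(self.states, seen):
            raise ValueError("transition graph is not connected")
        for tr in self.transitions:
            if tr.law.kind == "balance":
                self._check_cycle(tr)

    def _check_cycle(self, tr: Transition):
        cyc = tr.law.cycle
        edges = list(zip(cyc[:-1], cyc[1:]))
        if (tr.source, tr.target) not in edges and (tr.target, tr.source) not in edges:
            raise ValueError(
                f"balance cycle for {tr.source}->{tr.target} does not contain that edge"
            )
        by_pair = {(t.source, t.target): t for t in self.transitions}
        for a, b in edges:
            fwd, bwd = by_pair.get((a, b)), by_pair.get((b, a))
            if fwd is None or bwd is None:
                raise ValueError(
                    f"balance cycle edge {a}<->{b} is not bidirectional in the scheme"
                )
            for other in (fwd, bwd):
                if other is not tr and other.law.kind == "balance":
                    raise ValueError(
                        "balance cycle for "
                        f"{tr.source}->{tr.target} contains another derived rate "
                        f"({other.source}->{other.target}): circular derivation"
                    )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self._index[state]

    def transition(self, source: str, target: str) -> Transition:
        for tr in self.transitions:
            if tr.source == source and tr.target == target:
                return tr
        raise KeyError(f"no transition {source}->{target}")

    # -- rate evaluation ---------------------------------------------------

    def rate(self, source: str, target: str, params: ModelParameters, V: float) -> float:
        tr = self.transition(source, target)
        if tr.law.kind == "balance":
            return derive_reversibility_rate(self, params, tr.law.cycle, (source, target), V)
        return params.bind(tr.law)(V)

    def generator(self, params: ModelParameters, V: float) -> np.ndarray:
        """Generator (Q) matrix at voltage V: Q[i,j]=rate i→j, rows sum to 0."""
        if not np.isfinite(V):
            raise ValueError(f"membrane voltage must be finite, got {V!r}")
        n = self.n_states
        Q = np.zeros((n, n))
        for tr in self.transitions:
            i, j = self._index[tr.source], self._index[tr.target]
            Q[i, j] = self.rate(tr.source, tr.target, params, V)
        Q[np.diag_indices(n)] = -Q.sum(axis=1)
        return Q

    # -- cycles ------------------------------------------------------------

    def cycle_basis(self) -> list[tuple[str, ...]]:
        """Fundamental cycles (closed state walks) of the undirected graph."""
        pairs = {tuple(sorted((t.source, t.target))) for t in self.transitions}
        root = self.states[0]
        parent = {root: None}
        order = [root]
        adj = {s: [] for s in self.states}
        for a, b in pairs:
            adj[a].append(b)
            adj[b].append(a)
        for s in order:
            for nb in adj[s]:
                if nb not in parent:
                    parent[nb] = s
                    order.append(nb)
        tree = {tuple(sorted((s, p))) for s, p in parent.items() if p is not None}
        cycles = []
        for a, b in sorted(pairs - tree):
            pa, pb = [a], [b]
            while pa[-1] is not None:
                pa.append(parent[pa[-1]])
            while pb[-1] is not None:
                pb.append(parent[pb[-1]])
            pa, pb = pa[:-1], pb[:-1]
            common = (set(pa) & set(pb))
            ia = next(i for i, s in enumerate(pa) if s in common)
            ib = next(i for i, s in enumerate(pb) if s in common)
            walk = pa[: ia + 1] + pb[:ib][::-1] + [a]
            cycles.append(tuple(walk))
        return cycles

    def cycle_flux_ratio(self, params: ModelParameters, cycle, V: float) -> float:
        """Forward/backward rate-product ratio around a closed walk (1 at balance)."""
        fwd = bwd = 1.0
        for a, b in zip(cycle[:-1], cycle[1:]):
            fwd *= self.rate(a, b, params, V)
            bwd *= self.rate(b, a, params, V)
        return fwd / bwd

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        trs = []
        for t in self.transitions:
            d = {"from": t.source, "to": t.target, "law": t.law.kind}
            if t.law.param:
                d["param"] = t.law.param
            if t.law.by:
                d["by"] = t.law.by
                if t.law.power != 1:
                    d["power"] = t.law.power
            if t.law.cycle:
                d["cycle"] = list(t.law.cycle)
            if t.law.value is not None:
                d["value"] = t.law.value
            trs.append(d)
        return {
            "name": self.name,
            "states": list(self.states),
            "conducting": self.conducting,
            "transitions": trs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        trs = [
            Transition(
                source=t["from"],
                target=t["to"],
                law=LawSpec(
                    kind=t["law"],
                    param=t.get("param"),
                    by=t.get("by"),
                    power=t.get("power", 1),
                    cycle=tuple(t["cycle"]) if "cycle" in t else None,
                    value=t.get("value"),
                ),
            )
            for t in d["transitions"]
        ]
        return cls(d["states"], d["conducting"], trs, name=d.get("name", "scheme"))

    @classmethod
    def from_file(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def derive_reversibility_rate(scheme, params, cycle, edge, V) -> float:
    """Rate on ``edge=(source, target)`` enforcing detailed balance on ``cycle``.

    ``cycle`` is a closed walk of state names.  All other cycle edges must
    carry evaluable (non-derived) laws in both directions; the returned rate
    makes the product of rates along the walk equal the product against it.
    Rotating the walk's starting point leaves the result unchanged.
    """
    if cycle[0] != cycle[-1]:
        raise ValueError("cycle is not closed (first state must repeat last)")
    src, tgt = edge
    along = 1.0
    against = 1.0
    orientation = None
    for a, b in zip(cycle[:-1], cycle[1:]):
        if (a, b) == (src, tgt):
            orientation = "along"
            against *= scheme.rate(b, a, params, V)
            continue
        if (a, b) == (tgt, src):
            orientation = "against"
            along *= scheme.rate(a, b, params, V)
            continue
        along *= scheme.rate(a, b, params, V)
        against *= scheme.rate(b, a, params, V)
    if orientation is None:
        raise ValueError(f"edge {src}->{tgt} is not part of the cycle {cycle!r}")
    if orientation == "along":
        if along == 0:
            raise ZeroDivisionError("zero rate product along the cycle")
        return against / along
    if against == 0:
        raise ZeroDivisionError("zero rate product against the cycle")
    return along / against


def build_generator(scheme: KineticScheme, params: ModelParameters, V: float) -> np.ndarray:
    """Module-level convenience for :meth:`KineticScheme.generator`."""
    return scheme.generator(params, V)


def stationary_distribution(scheme: KineticScheme, params: ModelParameters, V: float) -> np.ndarray:
    """Stationary occupancy π with π·Q = 0, π ≥ 0, Σπ = 1.

    Raises if the generator is reducible or defective at V (non-unique or
    signed null space).
    """
    Q = scheme.generator(params, V)
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.linalg.norm(pi @ Q)
    scale = max(np.abs(Q).max(), 1.0)
    if resid > 1e-8 * scale or np.any(pi < -1e-10):
        raise np.linalg.LinAlgError(
            f"no valid stationary distribution at V={V} mV "
            f"(residual {resid:.2e}, min component {pi.min():.2e}); "
            "the generator may be reducible or defective"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
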