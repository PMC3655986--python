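"""Global rate-constant estimation from macroscopic current traces.

Fits selected rate-law parameters of a gating scheme directly to families
of voltage-clamp current traces by minimizing a normalized sum of squared
errors with a canonical global-best particle swarm (constriction
coefficients w = 0.729, c1 = c2 = 1.49445), refined every few generations
by a bounded golden-section line search along each coordinate of the
swarm's best point.  Rate-like parameters (pre-exponential ``k`` and
sigmoid ``g`` factors) are searched in log10 space since the model's rates
span several orders of magnitude; voltage factors and dimensionless scales
are searched linearly.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .protocols import VoltageProtocol
from .scheme import KineticScheme, ModelParameters
from .simulate import SimConfig, run_protocol

__all__ = ["FitProblem", "FitReport", "cost", "pso_gss_fit", "profile_parameter"]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _is_rate_like(name: str) -> bool:
    return name.endswith(".k") or name.endswith(".g")


@dataclass
class FitProblem:
    """A parameter-estimation problem over one scheme and ≥1 trace families.

    ``datasets`` pairs each protocol with its target current traces (one
    array per sweep, sampled exactly as ``run_protocol`` samples them under
    ``config``).  ``free`` maps dotted parameter names (``"alpha1.k"``,
    ``"rho1.g"``, ``"c"``) to finite (lower, upper) box bounds; every other
    parameter is held at its value in ``fixed``.  ``log_scale`` overrides
    the default log10 treatment of k/g-type parameters.
    """

    scheme: KineticScheme
    datasets: list[tuple[VoltageProtocol, list[np.ndarray]]]
    free: dict[str, tuple[float, float]]
    fixed: ModelParameters
    config: SimConfig = field(default_factory=SimConfig)
    log_scale: dict[str, bool] | None = None

    def __post_init__(self):
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
            self._check_referenced(name)
        self._norms = [
            max(np.max(np.abs(tr)) for tr in targets) or 1.0
            for _, targets in self.datasets
        ]

    def _check_referenced(self, name: str) -> None:
        base = name.split(".")[0]
        used = {t.law.param for t in self.scheme.transitions if t.law.param}
        used |= {t.law.by for t in self.scheme.transitions if t.law.by}
        if base not in used:
            raise ValueError(f"free parameter {name!r} is not referenced by the scheme")

    # -- transformed coordinates ------------------------------------------

    def names(self) -> list[str]:
        return sorted(self.free)

    def is_log(self, name: str) -> bool:
        if self.log_scale and name in self.log_scale:
            return self.log_scale[name]
        return _is_rate_like(name)

    def to_internal(self, name: str, value: float) -> float:
        return math.log10(value) if self.is_log(name) else value

    def from_internal(self, name: str, x: float) -> float:
        return 10.0**x if self.is_log(name) else x

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.to_internal(n, self.free[n][0]) for n in self.names()])
        hi = np.array([self.to_internal(n, self.free[n][1]) for n in self.names()])
        return lo, hi

    def params_from_vector(self, x: np.ndarray) -> ModelParameters:
        updates = {
            n: self.from_internal(n, xi) for n, xi in zip(self.names(), x)
        }
        return self.fixed.replace(**updates)


def cost(problem: FitProblem, params: ModelParameters) -> float:
    """Sum over protocols of peak-normalized SSE between model and targets."""
    total = 0.0
    for (protocol, targets), norm in zip(problem.datasets, problem._norms):
        traces = run_protocol(problem.scheme, params, protocol, problem.config)
        for tr, target in zip(traces, targets):
            resid = (tr.current - np.asarray(target)) / norm
            total += float(resid @ resid)
    return total


@dataclass
class FitReport:
    best_values: dict[str, float]
    best_params: ModelParameters
    best_cost: float
    cost_trajectory: list[float]  # global-best cost per generation
    n_evaluations: int
    seed: int
    swarm_size: int
    iterations: int

    def summary(self) -> str:
        lines = [
            f"PSO-GSS fit: cost {self.best_cost:.6g} after {self.n_evaluations} "
            f"evaluations (swarm {self.swarm_size}, {self.iterations} generations, seed {self.seed})"
        ]
        for k, v in sorted(self.best_values.items()):
            lines.append(f"  {k:>12} = {v:.6g}")
        return "\n".join(lines)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "best_values": {k: float(v) for k, v in self.best_values.items()},
                    "best_cost": float(self.best_cost),
                    "cost_trajectory": [float(c) for c in self.cost_trajectory],
                    "n_evaluations": self.n_evaluations,
                    "seed": self.seed,
                    "swarm_size": self.swarm_size,
                    "iterations": self.iterations,
                },
                fh,
                sort_keys=False,
            )


def _golden_section(f, lo, hi, tol, max_iter=40):
    """Minimize f on [lo, hi] by golden-section search; returns (x, f(x))."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if abs(b - a) < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc < fd else (d, fd)


def pso_gss_fit(
    problem: FitProblem,
    swarm_size: int = 20,
    iterations: int = 40,
    seed: int = 0,
    gss_every: int = 10,
    inertia: float = 0.729,
    cognitive: float = 1.49445,
    social: float = 1.49445,
    gss_tol: float = 1e-4,
    verbose: bool = False,
) -> FitReport:
    """Global-best PSO over box-bounded (log-transformed) parameters.

    Every ``gss_every`` generations the global best is polished by a
    golden-section line search along each coordinate.  ``swarm_size=1`` with
    ``iterations=0`` simply evaluates and returns the initial sample.
    """
    rng = np.random.default_rng(seed)
    lo, hi = problem.internal_bounds()
    dim = len(lo)
    span = hi - lo

    pos = lo + rng.random((swarm_size, dim)) * span
    vel = (rng.random((swarm_size, dim)) - 0.5) * span * 0.2
    evals = 0

    def evaluate(x):
        nonlocal evals
        evals += 1
        try:
            c = cost(problem, problem.params_from_vector(x))
        except (FloatingPointError, ValueError, np.linalg.LinAlgError):
            return np.inf
        return c if np.isfinite(c) else np.inf

    pcost = np.array([evaluate(x) for x in pos])
    if not np.any(np.isfinite(pcost)):
        raise RuntimeError(
            "every particle produced a non-finite cost at initialization; "
            f"first particle: {problem.params_from_vector(pos[0])._entries}"
        )
    pbest = pos.copy()
    pbest_cost = pcost.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
    trajectory = [gbest_cost]

    for it in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        vel = inertia * vel + cognitive * r1 * (pbest - pos) + social * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(swarm_size):
            ci = evaluate(pos[i])
            if ci < pbest_cost[i]:
                pbest[i], pbest_cost[i] = pos[i].copy(), ci
                if ci < gbest_cost:
                    gbest, gbest_cost = pos[i].copy(), float(ci)
        if gss_every and (it + 1) % gss_every == 0:
            for j in range(dim):
                def along(xj, j=j):
                    x = gbest.copy()
                    x[j] = xj
                    return evaluate(x)
                xj, cj = _golden_section(along, lo[j], hi[j], tol=gss_tol * max(span[j], 1e-12))
                if cj < gbest_cost:
                    gbest = gbest.copy()
                    gbest[j] = xj
                    gbest_cost = float(cj)
        trajectory.append(gbest_cost)
        if verbose:
            print(f"generation {it + 1}: best cost {gbest_cost:.6g}")

    values = {
        n: problem.from_internal(n, x) for n, x in zip(problem.names(), gbest)
    }
    return FitReport(
        best_values=values,
        best_params=problem.params_from_vector(gbest),
        best_cost=gbest_cost,
        cost_trajectory=trajectory,
        n_evaluations=evals,
        seed=seed,
        swarm_size=swarm_size,
        iterations=iterations,
    )


def profile_parameter(
    problem: FitProblem, best: ModelParameters, name: str, grid
) -> tuple[np.ndarray, np.ndarray]:
    """Cost profile along one parameter, all others held at ``best``."""
    grid = np.asarray(grid, float)
    costs = np.array([cost(problem, best.replace(**{name: float(v)})) for v in grid])
    return grid, costs
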