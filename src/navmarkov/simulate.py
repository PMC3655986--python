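"""Macroscopic current simulation: master-equation propagation over protocols.

State occupancies obey ``dp/dt = p · Q(V)`` with the generator Q constant
within each protocol segment.  Two propagators are provided:

* ``spectral`` — exact matrix-exponential solution via eigendecomposition of
  Q (per-voltage cached), with a robust ``scipy.linalg.expm`` fallback when
  the eigenvector basis is ill-conditioned;
* ``rk`` — fifth-order Runge–Kutta integration (Dormand–Prince pair via
  ``scipy.integrate.solve_ivp``) with a step-size cap, used as the
  independent cross-check.

Macroscopic current is ``I(t) = Gmax · P_open(t) · (V − E_rev)`` (inward
negative).  The default reversal potential is the Na⁺ Nernst potential for
140 mM external / 10 mM internal Na⁺ at 24 °C (≈ +67.5 mV); all shipped
analyses use normalized quantities, so Gmax and E_rev only set scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .protocols import Segment, VoltageProtocol
from .scheme import KineticScheme, ModelParameters, stationary_distribution

__all__ = [
    "SimConfig",
    "SimulatedTrace",
    "Propagator",
    "propagate_segment_spectral",
    "propagate_segment_rk",
    "run_sweep",
    "run_protocol",
    "write_traces",
    "read_traces",
]

#: Na+ Nernst potential, 140 mM out / 10 mM in, 24 degC
NA_REVERSAL_MV = 67.5


@dataclass(frozen=True)
class SimConfig:
    gmax: float = 1.0  # maximal conductance, arbitrary units
    e_rev: float = NA_REVERSAL_MV  # mV
    method: str = "spectral"  # "spectral" | "rk"
    dt: float | None = None  # override protocol sampling interval, ms
    rk_dt: float = 0.005  # RK step-size cap, ms
    max_segment_samples: int = 4000  # recording resolution cap per segment
    hold_mode: str = "stationary"  # "stationary" | "simulate"
    hold_duration: float = 10_000.0  # ms, for hold_mode="simulate"

    def __post_init__(self):
        if not (self.gmax > 0):
            raise ValueError("Gmax must be > 0")
        if self.method not in ("spectral", "rk"):
            raise ValueError(f"unknown propagator {self.method!r}")
        if self.hold_mode not in ("stationary", "simulate"):
            raise ValueError(f"unknown hold mode {self.hold_mode!r}")


@dataclass
class SimulatedTrace:
    """One sweep: time grid, occupancies, command voltage, current."""

    time: np.ndarray  # ms, starts at 0 = first non-holding segment
    voltage: np.ndarray  # mV command at each sample
    occupancy: np.ndarray  # (n_samples, n_states)
    current: np.ndarray  # Gmax * P_open * (V - E_rev)
    states: list[str]
    conducting: str
    sweep_value: float
    segment_bounds: list[tuple[int, int]]  # [start, end) sample index per segment
    segments: list[Segment] = field(default_factory=list)

    @property
    def open_probability(self) -> np.ndarray:
        return self.occupancy[:, self.states.index(self.conducting)]

    def segment_slice(self, index: int) -> slice:
        lo, hi = self.segment_bounds[index]
        return slice(lo, hi)

    def peak_current(self, segment: int | None = None) -> float:
        """Signed extremum of the current (within one segment if given)."""
        cur = self.current if segment is None else self.current[self.segment_slice(segment)]
        return float(cur[np.argmax(np.abs(cur))])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.time, "voltage_mV": self.voltage, "current": self.current})
        for j, s in enumerate(self.states):
            df[f"occ_{s}"] = self.occupancy[:, j]
        return df


def _sample_times(duration: float, dt: float, cap: int) -> np.ndarray:
    """Sample grid (0, duration], endpoint exact, at most ``cap`` points."""
    n = int(round(duration / dt))
    n = max(2, min(n, cap))
    return np.linspace(0.0, duration, n + 1)[1:]


class Propagator:
    """Occupancy propagation for one (scheme, params) pair.

    Spectral mode caches the eigendecomposition of Q per voltage; the
    contract is purely functional — identical inputs give identical outputs.
    """

    def __init__(self, scheme: KineticScheme, params: ModelParameters, config: SimConfig | None = None):
        self.scheme = scheme
        self.params = params
        self.config = config or SimConfig()
        self._eig: dict[float, tuple] = {}
        self._Q: dict[float, np.ndarray] = {}

    def generator(self, V: float) -> np.ndarray:
        V = float(V)
        if V not in self._Q:
            self._Q[V] = self.scheme.generator(self.params, V)
        return self._Q[V]

    def _eigensystem(self, V: float):
        V = float(V)
        if V not in self._eig:
            Q = self.generator(V)
            lam, U = np.linalg.eig(Q.T)
            try:
                Uinv = np.linalg.inv(U)
                cond = np.linalg.cond(U)
            except np.linalg.LinAlgError:
                Uinv, cond = None, np.inf
            self._eig[V] = (lam, U, Uinv, cond)
        return self._eig[V]

    def propagate(self, p0: np.ndarray, V: float, times: np.ndarray) -> np.ndarray:
        """Occupancies at ``times`` (ms, measured from segment start)."""
        p0 = np.asarray(p0, dtype=float)
        if abs(p0.sum() - 1.0) > 1e-6:
            raise ValueError(f"initial occupancy must sum to 1, got {p0.sum():.6f}")
        if self.config.method == "rk":
            occ = self._propagate_rk(p0, V, times)
        else:
            occ = self._propagate_spectral(p0, V, times)
        if not np.all(np.isfinite(occ)):
            raise FloatingPointError(
                f"non-finite occupancies propagating segment at V={V} mV"
            )
        # guard tiny negative round-off, keep conservation exact
        occ = np.clip(occ, 0.0, None)
        occ /= occ.sum(axis=1, keepdims=True)
        return occ

    def _propagate_spectral(self, p0, V, times):
        lam, U, Uinv, cond = self._eigensystem(V)
        if Uinv is not None and cond < 1e10:
            # p(t)^T = U exp(diag(lam) t) U^-1 p0^T
            w = Uinv @ p0
            phases = np.exp(np.outer(np.asarray(times, float), lam))  # (T, n)
            occ = (phases * w) @ U.T
            return occ.real
        Q = self.generator(V)
        times = np.asarray(times, float)
        occ = np.empty((len(times), len(p0)))
        p, t_prev = p0.copy(), 0.0
        for i, t in enumerate(times):
            p = p @ expm(Q * (t - t_prev))
            occ[i] = p
            t_prev = t
        return occ

    def _propagate_rk(self, p0, V, times):
        Q = self.generator(V)
        times = np.asarray(times, float)
        if times[-1] == 0.0:
            return np.tile(p0, (len(times), 1))
        sol = solve_ivp(
            lambda _t, p: p @ Q,
            t_span=(0.0, times[-1]),
            y0=p0,
            method="RK45",
            t_eval=times,
            max_step=self.config.rk_dt if self.config.rk_dt else np.inf,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"RK propagation failed at V={V} mV: {sol.message}")
        return sol.y.T

    def holding_occupancy(self, holding_V: float) -> np.ndarray:
        if self.config.hold_mode == "simulate":
            n = self.scheme.n_states
            p0 = np.full(n, 1.0 / n)
            return self.propagate(p0, holding_V, np.array([self.config.hold_duration]))[0]
        return stationary_distribution(self.scheme, self.params, holding_V)


def propagate_segment_spectral(scheme, params, p0, V, times) -> np.ndarray:
    """Spectral (matrix-exponential) propagation of ``dp/dt = p·Q(V)``."""
    return Propagator(scheme, params, SimConfig(method="spectral")).propagate(p0, V, np.asarray(times, float))


def propagate_segment_rk(scheme, params, p0, V, times, dt: float = 0.005) -> np.ndarray:
    """Fifth-order Runge–Kutta propagation with step cap ``dt`` (ms)."""
    return Propagator(scheme, params, SimConfig(method="rk", rk_dt=dt)).propagate(p0, V, np.asarray(times, float))


def run_sweep(
    scheme: KineticScheme,
    params: ModelParameters,
    protocol: VoltageProtocol,
    index: int,
    config: SimConfig | None = None,
    propagator: Propagator | None = None,
) -> SimulatedTrace:
    """Simulate one sweep: stationary hold, then chained segment propagation."""
    config = config or SimConfig()
    prop = propagator or Propagator(scheme, params, config)
    p0 = prop.holding_occupancy(protocol.holding)

    times_all, volts_all, occs_all, bounds = [], [], [], []
    t_offset, cursor = 0.0, 0
    segs = protocol.sweep_segments(index)
    base_dt = config.dt or protocol.dt
    for seg in segs:
        dt = seg.dt or base_dt
        local = _sample_times(seg.duration, dt, config.max_segment_samples)
        occ = prop.propagate(p0, seg.voltage, local)
        p0 = occ[-1]
        times_all.append(t_offset + local)
        volts_all.append(np.full(local.shape, seg.voltage))
        occs_all.append(occ)
        bounds.append((cursor, cursor + len(local)))
        cursor += len(local)
        t_offset += seg.duration

    time = np.concatenate(times_all)
    voltage = np.concatenate(volts_all)
    occupancy = np.vstack(occs_all)
    p_open = occupancy[:, scheme.index(scheme.conducting)]
    current = config.gmax * p_open * (voltage - config.e_rev)
    return SimulatedTrace(
        time=time,
        voltage=voltage,
        occupancy=occupancy,
        current=current,
        states=list(scheme.states),
        conducting=scheme.conducting,
        sweep_value=protocol.sweep.values[index],
        segment_bounds=bounds,
        segments=list(segs),
    )


def run_protocol(
    scheme: KineticScheme,
    params: ModelParameters,
    protocol: VoltageProtocol,
    config: SimConfig | None = None,
) -> list[SimulatedTrace]:
    """One trace per sweep, ordered as the sweep value list."""
    config = config or SimConfig()
    prop = Propagator(scheme, params, config)
    return [
        run_sweep(scheme, params, protocol, i, config, propagator=prop)
        for i in range(protocol.n_sweeps)
    ]


# ---------------------------------------------------------------------------
# trace I/O: long-format delimited text + YAML metadata sidecar
# ---------------------------------------------------------------------------


def write_traces(traces: list[SimulatedTrace], path, metadata: dict | None = None) -> None:
    """Write sweeps as one long-format TSV plus a ``.meta.yaml`` sidecar."""
    path = Path(path)
    frames = []
    for i, tr in enumerate(traces):
        df = tr.to_frame()
        df.insert(0, "sweep", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    meta = {
        "states": traces[0].states,
        "conducting": traces[0].conducting,
        "sweeps": [
            {
                "sweep_value": float(tr.sweep_value),
                "segment_bounds": [[int(a), int(b)] for a, b in tr.segment_bounds],
                "segments": [{"duration": s.duration, "voltage": s.voltage} for s in tr.segments],
            }
            for tr in traces
        ],
    }
    if metadata:
        meta.update(metadata)
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_traces(path) -> tuple[list[SimulatedTrace], dict]:
    """Read traces written by :func:`write_traces` back losslessly."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(path.suffix + ".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    states = meta["states"]
    occ_cols = [f"occ_{s}" for s in states]
    traces = []
    for i, sw in enumerate(meta["sweeps"]):
        sub = df[df["sweep"] == i]
        traces.append(
            SimulatedTrace(
                time=sub["time_ms"].to_numpy(),
                voltage=sub["voltage_mV"].to_numpy(),
                occupancy=sub[occ_cols].to_numpy(),
                current=sub["current"].to_numpy(),
                states=list(states),
                conducting=meta["conducting"],
                sweep_value=sw["sweep_value"],
                segment_bounds=[tuple(b) for b in sw["segment_bounds"]],
                segments=[Segment(duration=s["duration"], voltage=s["voltage"]) for s in sw["segments"]],
            )
        )
    return traces, meta
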