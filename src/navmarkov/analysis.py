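"""Trace reduction and curve fitting for voltage-clamp families.

Implements the standard electrophysiology analyses: peak-current
extraction, conductance–voltage (G–V) conversion, Boltzmann fits of
activation and steady-state availability, fractional-recovery curves with
mono-/bi-exponential fits, development-of-slow-inactivation fits, and
per-trace time-constant extraction.

Fitted forms (V in mV, t in ms unless noted):

* activation:    G/Gmax = 1 / (1 + exp((V50 − V)/k))
* availability:  I/Imax = 1 / (1 + exp((V − V50)/k))
* development:   y(t) = a + b·exp(−t/τ)
* mono recovery: y(t) = y∞ − A1·exp(−t/τ1)
* bi recovery:   y(t) = y∞ − A1·exp(−t/τ1) − A2·exp(−t/τ2),  τ1 < τ2

All fits are plain (unweighted) least squares with deterministic,
derivative-free initial guesses, so identical inputs give identical fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from lmfit import Model

from .simulate import SimulatedTrace

__all__ = [
    "BoltzmannFit",
    "MonoExpFit",
    "BiExpFit",
    "peak_currents",
    "gv_curve",
    "fit_boltzmann_activation",
    "fit_boltzmann_availability",
    "fractional_recovery",
    "fit_recovery",
    "fit_development",
    "extract_time_constant",
]


class _FitResultBase:
    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"fit": type(self).__name__, **self.to_dict()}, fh, sort_keys=False)

    def summary(self) -> str:
        lines = [f"{type(self).__name__}"]
        for k, v in self.to_dict().items():
            lines.append(f"  {k:>12}: {v:.6g}" if isinstance(v, float) else f"  {k:>12}: {v}")
        return "\n".join(lines)


@dataclass
class BoltzmannFit(_FitResultBase):
    v50: float  # mV
    k: float  # mV, slope factor
    scale: float
    residual: float
    n_points: int


@dataclass
class MonoExpFit(_FitResultBase):
    tau: float  # ms
    amplitude: float
    offset: float
    residual: float
    n_points: int


@dataclass
class BiExpFit(_FitResultBase):
    tau1: float  # fast, ms
    tau2: float  # slow, ms
    fraction1: float  # A1/(A1+A2)
    fraction2: float
    amplitude1: float
    amplitude2: float
    offset: float
    residual: float
    n_points: int
    degenerate: bool = False  # second component unresolvable / negligible


# ---------------------------------------------------------------------------
# trace reductions
# ---------------------------------------------------------------------------


def peak_currents(traces: list[SimulatedTrace], segment: int) -> tuple[np.ndarray, np.ndarray]:
    """(sweep value, signed peak current in ``segment``) for each sweep."""
    values = np.array([tr.sweep_value for tr in traces])
    peaks = np.array([tr.peak_current(segment) for tr in traces])
    return values, peaks


def gv_curve(voltages, peaks, e_rev: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized conductance G(V)/Gmax from peak currents: G = I/(V − E_rev)."""
    voltages = np.asarray(voltages, float)
    peaks = np.asarray(peaks, float)
    driving = voltages - e_rev
    if np.any(driving == 0):
        raise ValueError("test voltage equals the reversal potential; conductance undefined")
    g = peaks / driving
    gmax = np.max(np.abs(g))
    if gmax == 0:
        raise ValueError("all conductances are zero; cannot normalize")
    return voltages, g / gmax


def fractional_recovery(
    traces: list[SimulatedTrace], p1_segment: int = 0, p2_segment: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Recovery ratios I(P2)/I(P1) vs interpulse interval for a two-pulse family."""
    intervals = np.array([tr.sweep_value for tr in traces])
    p1 = np.array([tr.peak_current(p1_segment) for tr in traces])
    p2 = np.array([tr.peak_current(p2_segment) for tr in traces])
    if np.any(p1 == 0):
        raise ValueError("prepulse peak current is zero; recovery ratio undefined")
    return intervals, p2 / p1


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------


def _boltzmann_rising(V, v50, k, scale):
    return scale / (1.0 + np.exp((v50 - V) / k))


def _boltzmann_falling(V, v50, k, scale):
    return scale / (1.0 + np.exp((V - v50) / k))


def _fit_boltzmann(V, y, falling: bool, fix_scale: bool = False) -> BoltzmannFit:
    V = np.asarray(V, float)
    y = np.asarray(y, float)
    order = np.argsort(V)
    V, y = V[order], y[order]
    if len(V) < 4:
        raise ValueError("need at least 4 points spanning the transition")
    span = V.max() - V.min()
    yy = y[::-1] if falling else y
    vv = V[::-1] if falling else V
    if not np.all(np.diff(yy) >= 0):  # tolerate slight non-monotonicity
        order2 = np.argsort(yy)
        yy, vv = yy[order2], vv[order2]
    lo_y, hi_y = y.min(), y.max()
    v50_0 = float(np.interp(0.5 * (lo_y + hi_y), yy, vv))
    # slope seed from the 25-75% transition width (a pure Boltzmann has
    # width = 2*ln(3)*k); a span-based seed can be off by an order of
    # magnitude and push the optimizer into a degenerate step solution
    q25 = float(np.interp(lo_y + 0.25 * (hi_y - lo_y), yy, vv))
    q75 = float(np.interp(lo_y + 0.75 * (hi_y - lo_y), yy, vv))
    k0 = max(abs(q75 - q25) / 2.2, 0.02 * span)
    model = Model(_boltzmann_falling if falling else _boltzmann_rising)
    pars = model.make_params(v50=v50_0, k=k0, scale=max(y.max(), 1e-12))
    pars["k"].set(min=0.02 * span)
    pars["scale"].set(min=1e-12)
    if fix_scale:
        pars["scale"].set(value=1.0, vary=False)
    out = model.fit(y, pars, V=V)
    if not out.success:
        raise RuntimeError(
            f"Boltzmann fit failed ({out.message}); initial guess v50={v50_0:.3g}, "
            f"k={0.25 * span:.3g}"
        )
    v50 = float(out.params["v50"].value)
    if not (V.min() - span <= v50 <= V.max() + span):
        raise RuntimeError(f"fitted V50={v50:.3g} mV far outside the data range")
    return BoltzmannFit(
        v50=v50,
        k=float(out.params["k"].value),
        scale=float(out.params["scale"].value),
        residual=float(np.sqrt(np.sum(out.residual**2))),
        n_points=len(V),
    )


def fit_boltzmann_activation(V, g_norm, fix_scale: bool = False) -> BoltzmannFit:
    """Rising Boltzmann fit to a normalized G–V curve.

    ``fix_scale=True`` pins the amplitude at 1 (the normalized two-parameter
    form, appropriate when the data are already G/Gmax).
    """
    return _fit_boltzmann(V, g_norm, falling=False, fix_scale=fix_scale)


def fit_boltzmann_availability(V, y_norm, fix_scale: bool = False) -> BoltzmannFit:
    """Falling Boltzmann fit to a normalized availability curve."""
    return _fit_boltzmann(V, y_norm, falling=True, fix_scale=fix_scale)


def _tau_seed(t, y) -> float:
    """Log-linear regression on the approach to the final value."""
    y_inf = y[-1]
    resid = np.abs(y - y_inf)
    mask = resid > max(1e-12, 1e-3 * resid.max())
    if mask.sum() < 2:
        return max(float(t[-1] - t[0]) / 3.0, 1e-6)
    slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
    return float(-1.0 / slope) if slope < 0 else max(float(t[-1] - t[0]) / 3.0, 1e-6)


def _mono(t, tau, amplitude, offset):
    return offset - amplitude * np.exp(-t / tau)


def _bi(t, tau1, tau2, a1, a2, offset):
    return offset - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)


def _fit_mono(t, y) -> MonoExpFit:
    model = Model(_mono)
    tau0 = _tau_seed(t, y)
    pars = model.make_params(tau=tau0, amplitude=y[-1] - y[0], offset=y[-1])
    pars["tau"].set(min=1e-9)
    out = model.fit(y, pars, t=t)
    return MonoExpFit(
        tau=float(out.params["tau"].value),
        amplitude=float(out.params["amplitude"].value),
        offset=float(out.params["offset"].value),
        residual=float(np.sqrt(np.sum(out.residual**2))),
        n_points=len(t),
    )


def fit_recovery(intervals, fractions, model: str = "mono") -> MonoExpFit | BiExpFit:
    """Fit fractional-recovery data to a mono- or bi-exponential rise.

    Bi-exponential components are reported with τ1 < τ2 and fractional
    amplitudes A1/(A1+A2), A2/(A1+A2).  A second component carrying < 1% of
    the total amplitude (or with unresolvable time constants, τ2/τ1 < 3) is
    flagged ``degenerate``.
    """
    t = np.asarray(intervals, float)
    y = np.asarray(fractions, float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if model == "mono":
        if len(t) < 5:
            raise ValueError("need at least 5 points for a mono-exponential fit")
        return _fit_mono(t, y)
    if model != "bi":
        raise ValueError(f"model must be 'mono' or 'bi', got {model!r}")
    if len(t) < 8:
        raise ValueError("need at least 8 points for a bi-exponential fit")

    # two-stage peel-off seeding: slow component from the late half,
    # fast component from the early residual
    late = t >= np.median(t)
    slow = _fit_mono(t[late], y[late])
    resid_early = (slow.offset - slow.amplitude * np.exp(-t / slow.tau)) - y
    tau1_0 = max(min(_tau_seed(t, y - resid_early), slow.tau / 10.0), t[0] / 10.0)

    m = Model(_bi)
    pars = m.make_params(
        tau1=tau1_0,
        tau2=max(slow.tau, 10 * tau1_0),
        a1=max(abs(y[-1] - y[0]) * 0.5, 1e-6),
        a2=max(abs(slow.amplitude) * 0.5, 1e-6),
        offset=y[-1],
    )
    pars["tau1"].set(min=1e-9)
    pars["tau2"].set(min=1e-9)
    pars["a1"].set(min=0)
    pars["a2"].set(min=0)
    out = m.fit(y, pars, t=t)
    tau1, tau2 = float(out.params["tau1"].value), float(out.params["tau2"].value)
    a1, a2 = float(out.params["a1"].value), float(out.params["a2"].value)
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    total = a1 + a2
    degenerate = total == 0 or min(a1, a2) / total < 0.01
    if tau2 / max(tau1, 1e-300) < 3:
        warnings.warn(
            f"bi-exponential components unresolvable (tau2/tau1 = {tau2 / tau1:.2f} < 3)",
            stacklevel=2,
        )
        degenerate = True
    return BiExpFit(
        tau1=tau1,
        tau2=tau2,
        fraction1=a1 / total if total else np.nan,
        fraction2=a2 / total if total else np.nan,
        amplitude1=a1,
        amplitude2=a2,
        offset=float(out.params["offset"].value),
        residual=float(np.sqrt(np.sum(out.residual**2))),
        n_points=len(t),
        degenerate=bool(degenerate),
    )


def fit_development(durations, peaks, normalize: bool = True) -> MonoExpFit:
    """Fit ``a + b·exp(−t/τ)`` to remaining peak current vs prepulse duration.

    Peaks are normalized to the shortest-duration peak before fitting.
    """
    t = np.asarray(durations, float)
    y = np.asarray(peaks, float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if len(t) < 5:
        raise ValueError("need at least 5 durations")
    if normalize:
        ref = np.abs(y[0])
        if ref == 0:
            raise ValueError("shortest-duration peak is zero; cannot normalize")
        y = np.abs(y) / ref

    def decay(t, tau, a, b):
        return a + b * np.exp(-t / tau)

    m = Model(decay)
    pars = m.make_params(tau=_tau_seed(t, y), a=y[-1], b=y[0] - y[-1])
    pars["tau"].set(min=1e-9)
    out = m.fit(y, pars, t=t)
    return MonoExpFit(
        tau=float(out.params["tau"].value),
        amplitude=float(out.params["b"].value),
        offset=float(out.params["a"].value),
        residual=float(np.sqrt(np.sum(out.residual**2))),
        n_points=len(t),
    )


def extract_time_constant(
    trace: SimulatedTrace, phase: str, segment: int | None = None
) -> MonoExpFit:
    """Mono-exponential time constant of one kinetic phase of a trace.

    ``activation``   — rise from segment start to the current peak;
    ``inactivation`` — decay from 110% of time-to-peak to segment end;
    ``deactivation`` — tail decay from the segment's peak to its end.
    """
    if phase not in ("activation", "inactivation", "deactivation"):
        raise ValueError(f"unknown phase {phase!r}")
    if segment is None:
        segment = len(trace.segment_bounds) - 1 if phase == "deactivation" else 0
    sl = trace.segment_slice(segment)
    t = trace.time[sl]
    cur = trace.current[sl]
    ipk = int(np.argmax(np.abs(cur)))
    if phase == "activation":
        lo, hi = 0, ipk + 1
    elif phase == "inactivation":
        t_peak = t[ipk] - t[0]
        lo = ipk + int(np.searchsorted(t[ipk:] - t[0], 1.1 * t_peak))
        hi = len(t)
    else:  # deactivation tail
        lo, hi = ipk, len(t)
    if hi - lo < 4:
        raise ValueError(
            f"degenerate {phase} window in segment {segment} "
            f"(peak at sample {ipk} of {len(t)}): too few samples to fit"
        )
    return _fit_mono(t[lo:hi] - t[lo], cur[lo:hi])
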