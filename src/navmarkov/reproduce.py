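"""Reproduction of the published simulated kinetic characteristics.

Runs the packaged default models through the standard protocol/analysis
pipeline and reports the derived kinetic quantities next to the published
whole-cell simulation values the default wiring was reconstructed against:
activation and availability midpoints, recovery time constants at four
holding voltages, the bi-exponential slow-recovery parameters after a
prolonged prepulse, and the development time constant of slow inactivation.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    fit_boltzmann_activation,
    fit_boltzmann_availability,
    fit_development,
    fit_recovery,
    fractional_recovery,
    gv_curve,
    peak_currents,
)
from .models import build_model_I, build_model_II, default_parameters
from .protocols import (
    activation_protocol,
    availability_protocol,
    recovery_protocol,
    slow_inactivation_development_protocol,
)
from .simulate import SimConfig, run_protocol

__all__ = ["REFERENCE", "compute_reproduction", "reproduction_table"]

#: published simulated values (value, unit, tolerance) for the default models
REFERENCE = {
    "activation_v50_mV": (-34.0, "mV", 1.0),
    "availability_v50_model_I_mV": (-89.2, "mV", 1.0),
    "availability_v50_model_II_mV": (-89.7, "mV", 1.0),
    "recovery_tau_minus120_ms": (5.6, "ms", 0.10),
    "recovery_tau_minus110_ms": (11.9, "ms", 0.10),
    "recovery_tau_minus100_ms": (26.6, "ms", 0.10),
    "recovery_tau_minus90_ms": (49.6, "ms", 0.10),
    "slow_recovery_tau_ms": (557.2, "ms", 0.10),
    "fast_recovery_fraction_pct": (77.0, "%", 5.0),
    "slow_inactivation_development_tau_s": (1.58, "s", 0.10),
}


def compute_reproduction(config: SimConfig | None = None, progress=None) -> dict[str, float]:
    """Recompute every reference quantity from scratch with the default models.

    Returns a mapping from quantity name to the computed value (same units
    as :data:`REFERENCE`).  Runs in a few minutes on one CPU.
    """
    config = config or SimConfig()
    params = default_parameters()
    model_I = build_model_I(params)
    model_II = build_model_II(params)
    out: dict[str, float] = {}

    def note(msg):
        if progress:
            progress(msg)

    note("activation G-V (31 sweeps, Model I)")
    traces = run_protocol(model_I, params, activation_protocol(), config)
    v, peaks = peak_currents(traces, 0)
    _, g = gv_curve(v, peaks, config.e_rev)
    out["activation_v50_mV"] = fit_boltzmann_activation(v, g, fix_scale=True).v50

    for name, scheme in (
        ("availability_v50_model_I_mV", model_I),
        ("availability_v50_model_II_mV", model_II),
    ):
        note(f"steady-state availability ({scheme.name})")
        traces = run_protocol(scheme, params, availability_protocol(), config)
        v, peaks = peak_currents(traces, 1)
        y = np.abs(peaks) / np.max(np.abs(peaks))
        out[name] = fit_boltzmann_availability(v, y, fix_scale=True).v50

    for name, rv in (
        ("recovery_tau_minus120_ms", -120.0),
        ("recovery_tau_minus110_ms", -110.0),
        ("recovery_tau_minus100_ms", -100.0),
        ("recovery_tau_minus90_ms", -90.0),
    ):
        note(f"two-pulse recovery at {rv:g} mV (Model I)")
        traces = run_protocol(model_I, params, recovery_protocol(30.0, rv), config)
        t, f = fractional_recovery(traces)
        out[name] = fit_recovery(t, f, "mono").tau

    note("two-pulse recovery, 1000 ms prepulse (Model II)")
    traces = run_protocol(model_II, params, recovery_protocol(1000.0, -120.0), config)
    t, f = fractional_recovery(traces)
    bi = fit_recovery(t, f, "bi")
    out["slow_recovery_tau_ms"] = bi.tau2
    out["fast_recovery_fraction_pct"] = 100.0 * bi.fraction1

    note("development of slow inactivation (Model II)")
    traces = run_protocol(model_II, params, slow_inactivation_development_protocol(), config)
    d, peaks = peak_currents(traces, 2)
    out["slow_inactivation_development_tau_s"] = fit_development(d, peaks).tau / 1000.0
    return out


def reproduction_table(computed: dict[str, float]) -> tuple[str, bool]:
    """Format computed-vs-reference rows; returns (table text, all passed)."""
    lines = [f"{'quantity':38s} {'computed':>10s} {'reference':>10s} {'unit':>4s}  status"]
    all_ok = True
    for name, (ref, unit, tol) in REFERENCE.items():
        val = computed.get(name)
        if val is None:
            all_ok = False
            lines.append(f"{name:38s} {'-':>10s} {ref:10.2f} {unit:>4s}  MISSING")
            continue
        if unit == "mV":
            ok = abs(val - ref) <= max(tol, 0.02 * abs(ref))
        elif unit == "%":
            ok = abs(val - ref) <= tol
        else:
            ok = abs(val / ref - 1.0) <= tol
        all_ok &= ok
        lines.append(
            f"{name:38s} {val:10.3f} {ref:10.2f} {unit:>4s}  {'pass' if ok else 'FAIL'}"
        )
    return "\n".join(lines), all_ok
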