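"""Curve reductions and fitters: exact recovery on noiseless data."""

import numpy as np
import pytest

from navmarkov import (
    SimConfig,
    activation_protocol,
    fit_boltzmann_activation,
    fit_boltzmann_availability,
    fit_development,
    fit_recovery,
    fractional_recovery,
    gv_curve,
    peak_currents,
    run_protocol,
    run_sweep,
)
from navmarkov.simulate import SimulatedTrace
from navmarkov.synth import make_boltzmann_samples, make_exp_samples


def _trace_with_current(t, current):
    n = len(t)
    return SimulatedTrace(
        time=t,
        voltage=np.full(n, -10.0),
        occupancy=np.column_stack([np.ones(n), np.zeros(n)]),
        current=current,
        states=["C", "O"],
        conducting="O",
        sweep_value=-10.0,
        segment_bounds=[(0, n)],
    )


def test_peak_current_zero_and_injected():
    t = np.linspace(0, 2, 201)
    flat = _trace_with_current(t, np.zeros_like(t))
    assert flat.peak_current(0) == 0.0
    bump = -np.exp(-((t - 0.6) ** 2) / 0.005)
    tr = _trace_with_current(t, bump)
    assert tr.peak_current(0) == pytest.approx(-1.0)
    v, p = peak_currents([tr], 0)
    assert p[0] == pytest.approx(-1.0)


def test_gv_curve_flat_for_ohmic_peaks():
    V = np.arange(-90.0, 61.0, 5.0)
    e_rev = 67.5
    peaks = 0.8 * (V - e_rev)  # conductance exactly constant
    _, g = gv_curve(V, peaks, e_rev)
    assert np.allclose(g, 1.0)
    assert np.max(np.abs(g)) == 1.0


def test_gv_curve_rejects_reversal_voltage():
    with pytest.raises(ValueError, match="reversal"):
        gv_curve([0.0, 67.5], [1.0, 0.0], 67.5)


def test_simulated_gv_monotone_over_rising_limb(model_I, params, config):
    traces = run_protocol(model_I, params, activation_protocol(dt=0.05), config)
    v, peaks = peak_currents(traces, 0)
    _, g = gv_curve(v, peaks, config.e_rev)
    sel = (v >= -90) & (v <= 0)
    assert np.all(np.diff(g[sel]) >= -1e-3)


@pytest.mark.parametrize("v50,k,falling,fitter", [
    (-34.5, 7.2, False, fit_boltzmann_activation),
    (-89.1, 5.5, True, fit_boltzmann_availability),
])
def test_boltzmann_fit_recovers_noiseless_truth(v50, k, falling, fitter):
    V, y = make_boltzmann_samples(v50, k, np.arange(-120.0, 21.0, 5.0), falling=falling)
    fit = fitter(V, y)
    assert fit.v50 == pytest.approx(v50, abs=1e-8)
    assert fit.k == pytest.approx(k, abs=1e-8)
    assert fit.residual < 1e-8
    # permutation invariance
    order = np.argsort(np.sin(V))  # deterministic shuffle
    fit2 = fitter(V[order], y[order])
    assert fit2.v50 == pytest.approx(fit.v50, abs=1e-10)


def test_mono_recovery_fit_recovers_truth():
    t, y = make_exp_samples(np.geomspace(0.3, 40.0, 20), [5.1], [0.9], offset=1.0)
    fit = fit_recovery(t, y, "mono")
    assert fit.tau == pytest.approx(5.1, rel=1e-6)
    assert fit.offset == pytest.approx(1.0, rel=1e-8)


def test_bi_recovery_fit_recovers_truth():
    t = np.geomspace(0.5, 5000.0, 40)
    _, y = make_exp_samples(t, [5.2, 596.3], [0.78, 0.22], offset=1.0)
    fit = fit_recovery(t, y, "bi")
    assert fit.tau1 == pytest.approx(5.2, rel=1e-4)
    assert fit.tau2 == pytest.approx(596.3, rel=1e-4)
    assert fit.fraction1 == pytest.approx(0.78, rel=1e-4)
    assert fit.fraction2 == pytest.approx(0.22, rel=1e-4)
    assert not fit.degenerate


def test_bi_fit_on_mono_data_flags_degenerate_component():
    t = np.geomspace(0.3, 60.0, 24)
    _, y = make_exp_samples(t, [5.1], [0.9], offset=1.0)
    mono = fit_recovery(t, y, "mono")
    bi = fit_recovery(t, y, "bi")
    assert bi.degenerate
    # the dominant component agrees with the mono fit
    dom_tau = bi.tau1 if bi.amplitude1 >= bi.amplitude2 else bi.tau2
    assert dom_tau == pytest.approx(mono.tau, rel=1e-2)


def test_development_fit_recovers_truth():
    t = np.geomspace(20.0, 12_000.0, 15)  # ms
    y = 0.35 + 0.65 * np.exp(-t / 1790.0)  # tau = 1.79 s
    fit = fit_development(t, y, normalize=False)
    assert fit.tau == pytest.approx(1790.0, rel=1e-6)
    # scaling all peaks by 2 before normalization leaves tau unchanged
    fit2 = fit_development(t, 2 * y)
    assert fit2.tau == pytest.approx(1790.0, rel=1e-6)


def test_development_fit_constant_data_has_no_amplitude():
    t = np.geomspace(10.0, 5000.0, 10)
    fit = fit_development(t, np.ones_like(t), normalize=False)
    assert abs(fit.amplitude) < 1e-8


def test_fractional_recovery_from_constructed_mono_family(model_I, params):
    """Recovery ratios rebuilt from a synthetic mono-exponential family."""
    taus = np.geomspace(1.0, 60.0, 10)
    truth = 1.0 - 0.95 * np.exp(-taus / 8.0)
    traces = []
    t = np.linspace(0, 20, 101)
    for interval, frac in zip(taus, truth):
        p1 = -1.0 * np.exp(-((t - 1.0) ** 2))
        p2 = frac * p1
        n = len(t)
        traces.append(
            SimulatedTrace(
                time=np.concatenate([t, t + 20, t + 20 + interval]),
                voltage=np.full(3 * n, -20.0),
                occupancy=np.ones((3 * n, 1)),
                current=np.concatenate([p1, np.zeros(n), p2]),
                states=["O"],
                conducting="O",
                sweep_value=interval,
                segment_bounds=[(0, n), (n, 2 * n), (2 * n, 3 * n)],
            )
        )
    intervals, fracs = fractional_recovery(traces)
    assert fracs == pytest.approx(truth, rel=1e-12)
    fit = fit_recovery(intervals, fracs, "mono")
    assert fit.tau == pytest.approx(8.0, rel=1e-6)


def test_extract_time_constant_pure_exponential():
    from navmarkov.analysis import extract_time_constant

    t = np.linspace(0, 10, 1001)
    decay = -2.0 * np.exp(-t / 1.0)
    tr = _trace_with_current(t, decay)
    fit = extract_time_constant(tr, "deactivation", segment=0)
    assert fit.tau == pytest.approx(1.0, rel=1e-6)
    # invariant to a constant baseline offset
    tr2 = _trace_with_current(t, decay - 0.3)
    fit2 = extract_time_constant(tr2, "deactivation", segment=0)
    assert fit2.tau == pytest.approx(1.0, rel=1e-6)


def test_inactivation_tau_matches_eigenvalue_scale(model_I, params, config):
    """The fitted current-decay time constant at -10 mV agrees with the
    relevant relaxation eigenvalue of the generator to within 30%."""
    from navmarkov.analysis import extract_time_constant

    prot = activation_protocol()
    idx = list(prot.sweep.values).index(-10.0)
    tr = run_sweep(model_I, params, prot, idx, config)
    fit = extract_time_constant(tr, "inactivation", segment=0)
    lam = np.linalg.eigvals(model_I.generator(params, -10.0))
    lam = np.sort(lam.real)
    # slowest mode faster than 20 ms but slower than activation (~0.2 ms)
    candidates = -1.0 / lam[(lam < -5e-2) & (lam > -5.0)]
    assert any(abs(fit.tau / tau - 1.0) < 0.3 for tau in candidates)


def test_extract_time_constant_degenerate_window():
    from navmarkov.analysis import extract_time_constant

    t = np.linspace(0, 1, 11)
    tr = _trace_with_current(t, -np.linspace(0, 1, 11))  # peak at the boundary
    with pytest.raises(ValueError, match="few samples|degenerate"):
        extract_time_constant(tr, "inactivation", segment=0)
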