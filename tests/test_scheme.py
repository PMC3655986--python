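"""Scheme structure, generator matrices, reversibility, stationary states."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navmarkov import (
    KineticScheme,
    LawSpec,
    ModelParameters,
    Transition,
    build_generator,
    derive_reversibility_rate,
    stationary_distribution,
)
from navmarkov.simulate import propagate_segment_rk

from conftest import two_state


def test_two_state_generator_matrix():
    scheme, params = two_state(r1=2.0, r2=5.0)
    Q = build_generator(scheme, params, -80.0)
    assert np.allclose(Q, [[-2.0, 2.0], [5.0, -5.0]])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(V=st.floats(-140, 60))
def test_generator_rows_sum_to_zero_both_models(V, model_I, model_II, params):
    for scheme in (model_I, model_II):
        Q = scheme.generator(params, V)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-10 * max(1.0, np.abs(Q).max())


def _four_state_cycle():
    """Square cycle with forward rates 2,3,4 and backward 1,6,known=1; the
    derived backward rate must be 4 so both cycle products equal 24."""
    fixed = lambda v: LawSpec(kind="fixed", value=v)
    trs = [
        Transition("A", "B", fixed(2.0)), Transition("B", "A", fixed(1.0)),
        Transition("B", "C", fixed(3.0)), Transition("C", "B", fixed(6.0)),
        Transition("C", "D", fixed(4.0)), Transition("D", "C", fixed(1.0)),
        Transition("D", "A", fixed(1.0)),
        Transition("A", "D", LawSpec(kind="balance", cycle=("A", "B", "C", "D", "A"))),
    ]
    return KineticScheme(["A", "B", "C", "D"], "A", trs), ModelParameters({})


def test_detailed_balance_derivation_forced_value():
    scheme, params = _four_state_cycle()
    # the derived A->D rate closes the cycle: forward product = 2*3*4*1 = 24,
    # backward product = 1*6*1*derived -> derived = 4
    assert scheme.rate("A", "D", params, 0.0) == pytest.approx(4.0)
    assert scheme.cycle_flux_ratio(params, ("A", "B", "C", "D", "A"), 0.0) == pytest.approx(1.0)


def test_derived_rate_invariant_to_cycle_rotation():
    scheme, params = _four_state_cycle()
    base = derive_reversibility_rate(scheme, params, ("A", "B", "C", "D", "A"), ("A", "D"), 0.0)
    rotated = derive_reversibility_rate(scheme, params, ("C", "D", "A", "B", "C"), ("A", "D"), 0.0)
    reversed_walk = derive_reversibility_rate(scheme, params, ("A", "D", "C", "B", "A"), ("A", "D"), 0.0)
    assert base == rotated == reversed_walk == pytest.approx(4.0)


@pytest.mark.parametrize("V", [-120.0, -60.0, 0.0])
def test_derived_rates_balance_their_cycles(model_I, model_II, params, V):
    """Every balance-derived rate closes its declared cycle exactly."""
    for scheme in (model_I, model_II):
        for tr in scheme.transitions:
            if tr.law.kind == "balance":
                ratio = scheme.cycle_flux_ratio(params, tr.law.cycle, V)
                assert abs(ratio - 1.0) < 1e-10


@pytest.mark.parametrize("V", [-120.0, -60.0, 0.0])
def test_slow_row_cycles_balance(model_II, params, V):
    """The four slow-inactivation squares balance by construction (the slow
    row copies the fast-inactivated row with uniform entry/exit rates)."""
    squares = [
        ("I11", "I12", "I22", "I21", "I11"),
        ("I12", "I13", "I23", "I22", "I12"),
        ("I13", "I14", "I24", "I23", "I13"),
    ]
    for cyc in squares:
        assert model_II.cycle_flux_ratio(params, cyc, V) == pytest.approx(1.0, abs=1e-10)


def test_stationary_two_state_closed_form():
    scheme, params = two_state(r1=1.0, r2=3.0)
    pi = stationary_distribution(scheme, params, 0.0)
    assert pi == pytest.approx([0.75, 0.25])


def test_stationary_matches_long_time_integration(model_II, params):
    """Stationary occupancy at -120 mV equals the long-time limit of an
    independent stiff integration of the master equation from a uniform
    start (20 s is ~37 times the slowest relaxation time)."""
    from scipy.integrate import solve_ivp

    pi = stationary_distribution(model_II, params, -120.0)
    Q = model_II.generator(params, -120.0)
    n = model_II.n_states
    sol = solve_ivp(
        lambda _t, p: p @ Q,
        t_span=(0.0, 20_000.0),
        y0=np.full(n, 1.0 / n),
        method="LSODA",
        jac=lambda _t, _p: Q.T,
        rtol=1e-10,
        atol=1e-12,
    )
    assert sol.success
    assert np.max(np.abs(sol.y[:, -1] - pi)) < 1e-8


def test_stationary_at_rest_mostly_closed(model_I, model_II, params):
    """At -120 mV essentially no channels are open (all closed/available)."""
    for scheme in (model_I, model_II):
        pi = stationary_distribution(scheme, params, -120.0)
        assert pi[scheme.index(scheme.conducting)] < 0.01
        assert pi.sum() == pytest.approx(1.0)


def test_scheme_validation_errors():
    fixed = lambda v: LawSpec(kind="fixed", value=v)
    with pytest.raises(ValueError, match="duplicate"):
        KineticScheme(
            ["A", "B"], "A",
            [Transition("A", "B", fixed(1)), Transition("A", "B", fixed(2)),
             Transition("B", "A", fixed(1))],
        )
    with pytest.raises(ValueError, match="unknown state"):
        KineticScheme(["A", "B"], "A", [Transition("A", "C", fixed(1))])
    with pytest.raises(ValueError, match="not connected"):
        KineticScheme(
            ["A", "B", "C"], "A",
            [Transition("A", "B", fixed(1)), Transition("B", "A", fixed(1))],
        )
    with pytest.raises(ValueError):
        Transition("A", "A", fixed(1))


def test_circular_balance_derivation_rejected():
    fixed = lambda v: LawSpec(kind="fixed", value=v)
    cyc = ("A", "B", "C", "A")
    trs = [
        Transition("A", "B", fixed(1)), Transition("B", "A", fixed(1)),
        Transition("B", "C", fixed(1)), Transition("C", "B", fixed(1)),
        Transition("C", "A", LawSpec(kind="balance", cycle=cyc)),
        Transition("A", "C", LawSpec(kind="balance", cycle=cyc)),
    ]
    with pytest.raises(ValueError, match="circular"):
        KineticScheme(["A", "B", "C"], "A", trs)


def test_balance_cycle_must_be_bidirectional():
    fixed = lambda v: LawSpec(kind="fixed", value=v)
    trs = [
        Transition("A", "B", fixed(1)),  # no B->A
        Transition("B", "C", fixed(1)), Transition("C", "B", fixed(1)),
        Transition("C", "A", fixed(1)),
        Transition("A", "C", LawSpec(kind="balance", cycle=("A", "B", "C", "A"))),
    ]
    with pytest.raises(ValueError, match="bidirectional"):
        KineticScheme(["A", "B", "C"], "A", trs)


def test_scheme_file_round_trip(model_II, tmp_path):
    path = tmp_path / "scheme.yaml"
    model_II.to_file(path)
    loaded = KineticScheme.from_file(path)
    assert loaded.to_dict() == model_II.to_dict()


def test_parameter_file_round_trip(params, tmp_path):
    path = tmp_path / "params.yaml"
    params.to_file(path)
    loaded = ModelParameters.from_file(path)
    assert dict(loaded) == dict(params)


def test_parameter_validation():
    with pytest.raises(ValueError, match="k must be > 0"):
        ModelParameters({"alpha1": {"k": -1.0, "n": 5.0}})
    with pytest.raises(ValueError, match="must be > 0"):
        ModelParameters({"c": -2.0})
    with pytest.raises(ValueError, match="expected keys"):
        ModelParameters({"weird": {"x": 1.0}})


def test_missing_parameter_reported(model_I, params):
    incomplete = ModelParameters({k: v for k, v in params.items() if k != "rho2"})
    with pytest.raises(KeyError, match="rho2"):
        model_I.generator(incomplete, -80.0)
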