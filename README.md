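# navmarkov

Markov-model toolkit for the gating kinetics of the cardiac voltage-gated
sodium channel Nav1.5, for electrophysiologists and modelers who want to
simulate whole-cell Na⁺ currents, analyze them with the standard curve
fits, and estimate rate constants directly from current traces.

Nav1.5 carries the fast inward current of the cardiac action potential.
Besides millisecond-scale fast inactivation it exhibits *slow*
inactivation: with prolonged depolarization channels enter a second,
deeper non-conducting state, and recovery becomes bi-exponential
(milliseconds plus hundreds of milliseconds) — a behavior linked to
conduction disease. `navmarkov` ships two two-step-inactivation gating
schemes with a best-fit parameter set:

* **Model I** — 8 states: closed C1⇄C2⇄C3⇄O plus fast-inactivated
  I11–I14. Fast inactivation enters from the open state (O→I14); recovery
  drains the inactivated row toward I11 and exits by the rate-limiting
  I11→C1 step.
* **Model II** — Model I plus slow-inactivated I21–I24 beneath the fast
  row (entry ρ3, exit φ3), reproducing slow inactivation, its ~1.6 s
  development, and bi-exponential recovery.

State occupancies follow the master equation `dp/dt = p·Q(V)` with a
generator matrix built from declarative, voltage-dependent rate laws
(`k·exp(V/n)`, a saturating sigmoid, scaled copies, and rates derived from
microscopic reversibility of reaction cycles). Macroscopic current is
`I = Gmax·P_open·(V − E_rev)`. Schemes, parameters, protocols and traces
all round-trip through plain-text files; see `docs/methods.md` for the
model, its numerical treatment, and known limitations.

## Worked example

Simulate steady-state availability and slow recovery of the 12-state
model, then fit the standard curves:

```python
import numpy as np
from navmarkov import (
    build_model_II, default_parameters, SimConfig,
    availability_protocol, recovery_protocol, run_protocol,
    peak_currents, fit_boltzmann_availability, fractional_recovery, fit_recovery,
)

params = default_parameters()          # packaged best-fit rate constants
model = build_model_II(params)         # 12-state two-step inactivation scheme
config = SimConfig()                   # Gmax = 1, E_rev = +67.5 mV, spectral propagator

# availability: 500 ms conditioning steps, 20 ms test pulse at -10 mV
traces = run_protocol(model, params, availability_protocol(), config)
volts, peaks = peak_currents(traces, segment=1)
avail = np.abs(peaks) / np.max(np.abs(peaks))
fit = fit_boltzmann_availability(volts, avail, fix_scale=True)
print(f"availability midpoint V50 = {fit.v50:.1f} mV, slope k = {fit.k:.1f} mV")

# two-pulse recovery after a 1000 ms prepulse at -20 mV
traces = run_protocol(model, params, recovery_protocol(P1=1000.0, recovery_V=-120.0), config)
intervals, fractions = fractional_recovery(traces)
bi = fit_recovery(intervals, fractions, model="bi")
print(f"recovery after a 1 s prepulse: tau_fast = {bi.tau1:.1f} ms ({100*bi.fraction1:.0f}%), "
      f"tau_slow = {bi.tau2:.0f} ms ({100*bi.fraction2:.0f}%)")
```

This prints:

```
availability midpoint V50 = -89.2 mV, slope k = 7.7 mV
recovery after a 1 s prepulse: tau_fast = 5.1 ms (78%), tau_slow = 534 ms (22%)
```

Half the channels are unavailable after holding near −89 mV, and after a
one-second depolarization 22% of the current recovers on the
half-second time scale of slow inactivation while the rest recovers within
milliseconds.

The same workflows are available from the shell:

```sh
navmarkov simulate --model model_II --protocol availability --out avail.tsv
navmarkov analyze avail.tsv --analysis availability --out fit.yaml
navmarkov synth --protocol recovery --p1 1000 --sigma 0.02 --seed 1 --out noisy.tsv
navmarkov reproduce
```

`navmarkov fit` estimates free rate-law parameters from trace families by
particle-swarm optimization with golden-section refinement (see
`navmarkov.fitting`).

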