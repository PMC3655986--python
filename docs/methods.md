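# Methods

## The model

`navmarkov` implements macroscopic (ensemble-mean) Markov models of the
cardiac voltage-gated sodium channel Nav1.5. A channel occupies one of a
small set of conformational states — closed (C1–C3), open (O),
fast-inactivated (I11–I14) and, in the 12-state model, slow-inactivated
(I21–I24) — and moves between them with voltage-dependent rates. The state
occupancy row vector `p(t)` obeys the master equation

    dp/dt = p · Q(V),

where the generator matrix `Q(V)` holds the transition rate from state i to
state j in entry (i, j) and the negative row sums on the diagonal.
Macroscopic current is the ideal-clamp ohmic form

    I(t) = Gmax · P_open(t) · (V − E_rev),

inward negative. `Gmax` defaults to 1 (arbitrary units) and `E_rev` to the
Na⁺ Nernst potential for 140 mM external / 10 mM internal Na⁺ at 24 °C
(+67.5 mV). Every shipped analysis is normalized, so these two constants
set scale only.

### Rate laws

Each transition carries one of four laws (rates in 1/ms, V in mV):

| law | form | role |
|---|---|---|
| exponential | `k·exp(V/n)` | most transitions; negative `n` gives rates that grow with hyperpolarization |
| sigmoid | `g/(1+exp(−(V+a)/f))` | saturating rates (closed-state inactivation) |
| scaled | `c^m ·` another law | row-to-row copies via the dimensionless factor `c` |
| balance-derived | fixed by microscopic reversibility of a declared reaction cycle | the O→C3 deactivation rate |

A balance-derived rate has no free parameters: at every voltage it takes
whatever value makes the product of rates around its cycle equal the
product against the cycle, so the cycle carries no net flux at equilibrium.

### The shipped schemes

Schemes are fully declarative: the packaged YAML files
(`navmarkov/data/model_I.yaml`, `model_II.yaml`) list states, the
conducting state, and every transition with its law, and can be edited
without touching code. The default 8-state wiring is:

| edge | forward | backward |
|---|---|---|
| C1↔C2 | c·α1 | β1 |
| C2↔C3 | α2 | β2 |
| C3↔O | c³·α1 | β3 (derived from the outer ring cycle) |
| O↔I14 | ρ2 | c·φ2 |
| I11↔I12 | α1 | β1/c² |
| I12↔I13 | α2/c | β2/c³ |
| I13↔I14 | c²·α1 | β2/c² |
| C1↔I11 | down c·ρ1 | up φ1 |
| C2↔I12 | down ρ1 | up φ2 |
| C3↔I13 | down ρ1 | up c·φ2 |

The 12-state model appends a slow-inactivated row that copies the
fast-inactivated row's horizontal rates exactly, coupled at every column by
the slow entry rate ρ3 (down) and slow exit rate φ3 (up). Because the two
rows are identical and the couplings uniform, all four slow squares satisfy
detailed balance by construction.

This wiring is a reconstruction. The published description of the model
fixes the topology (three closed states in series with the open state, a
fast-inactivated row entered from O into I14 and left toward C1 via
I13→I12→I11, and a slow row beneath it) and the full parameter table, but
not which named rate sits on which edge. We resolved the assignment by
requiring the packaged parameter set to reproduce the published simulated
kinetic characteristics (activation and availability midpoints, the four
fast recovery time constants, the bi-exponential slow recovery, and the
development of slow inactivation — the quantities `scripts/acceptance.py`
recomputes), searching over several hundred structurally consistent
alternatives. Key features the data force:

* φ1 is the rate-limiting recovery step I11→C1: 1/φ1 at −120…−90 mV
  reproduces the fast recovery time constants almost by itself, and the
  fast-inactivated row must drain toward I11 through fast backward rates.
* The closed-state inactivation rates must saturate with depolarization —
  hence the sigmoid ρ1 on the C→I verticals. Any exponentially growing
  entry law steep enough to place the availability midpoint near −89 mV
  overwhelms activation at depolarized voltages and destroys the G–V curve.
* The last activation step C3→O must be fast (a c-scaled copy of α1): the
  total ladder transit time at −34 mV has to stay below the ~0.8 ms fast
  inactivation time for the G–V midpoint to sit at −34 mV.
* The inactivated row sits "left-shifted" relative to the closed row
  (equilibria shifted by ≈c² per column), which sets how the recovery rate
  steepens between −90 and −120 mV.
* 1/φ3(−120 mV) ≈ 535 ms matches the slow recovery time constant, and ρ3
  (≈1/3.2 s, nearly voltage-independent) with the φ3 back-flux yields the
  ≈1.6 s development of slow inactivation and a ~22% slow amplitude after a
  1 s prepulse.

Two caveats follow honestly from this reconstruction and are discussed
under Limitations: the α3 law is packaged but unused by the default wiring,
and the three closed↔inactivated squares do not balance.

### Parameters

The packaged set (`navmarkov/data/table1.yaml`) is shared by both models:
α1–α3, β1–β2, φ1–φ3, ρ2, ρ3 as (k, n) exponential pairs; ρ1 as a (g, a, f)
sigmoid; the dimensionless scale c = 2.146. Pre-exponential factors are in
1/ms, voltage factors in mV. User parameter files are flat YAML mappings of
the same shape.

## Protocol simulation

Protocols are piecewise-constant command-voltage segments with exactly one
varying slot per sweep family (a segment's voltage or duration). Builders
reproduce the five standard Nav1.5 protocols:

* activation: hold −120 mV, 20 ms steps −90…+60 mV in 5 mV increments;
* deactivation: 0.25 ms at −10 mV, then 20 ms tails −100…−30 mV;
* availability: 500 ms conditioning −120…0 mV in 10 mV steps, 20 ms test
  at −10 mV;
* two-pulse recovery: prepulse P1 (default 30 ms) at −20 mV, a variable
  interval at the recovery voltage, then a 20 ms test pulse at −20 mV.
  The prepulse/test voltage is configurable; −20 mV matches the
  development protocol, whose pulse voltage is documented. Default interval
  grids are log-spaced, 0.5–200 ms for P1 = 30 ms and 0.5–5000 ms for
  P1 = 1000 ms, covering both recovery components;
* development of slow inactivation: −20 mV prepulses of varying duration,
  a 30 ms interpulse at −120 mV that removes fast inactivation, and a
  20 ms test pulse at −20 mV.

Sweeps start from the exact stationary distribution at the holding
potential (solved from π·Q = 0) rather than a long simulated hold; a
finite-hold mode (`SimConfig(hold_mode="simulate")`) exists for
validation. Within a segment the default propagator is spectral:
`p(t) = p0·exp(Q t)` evaluated through an eigendecomposition of Q cached
per (scheme, parameters, voltage), with a `scipy.linalg.expm` fallback when
the eigenvector basis is ill-conditioned (condition number above 1e10).
Segment endpoints are therefore exact regardless of the recording grid. A
fifth-order Runge–Kutta propagator (Dormand–Prince via
`scipy.integrate.solve_ivp`, step cap 0.005 ms, tolerances 1e-10/1e-12)
serves as the independent cross-check; the two agree to better than 1e-6 in
occupancy on both models. Note the generator is stiff (fastest rates of
order 10³–10⁴/ms at −120 mV), so the explicit RK route is only practical
for short segments — the spectral path is the workhorse.

Recording: the default sampling interval is 0.01 ms (the upper end of
typical 10–100 kHz digitization); long conditioning/interval segments are
recorded coarsely (per-segment `dt`, plus a 4000-sample cap per segment)
since only their endpoint occupancy matters. Peaks are the signed extremum
of the current within a segment without sub-sample interpolation — at
0.01 ms sampling the bias on ~1 ms kinetics is negligible.

## Curve analysis

Fitted forms (plain unweighted least squares via lmfit, deterministic
derivative-free seeding):

* activation G–V: `G/Gmax = 1/(1+exp((V50−V)/k))` with
  `G = I_peak/(V−E_rev)` normalized to its maximum;
* availability: `I/Imax = 1/(1+exp((V−V50)/k))`;
* development: `y(t) = a + b·exp(−t/τ)`, peaks normalized to the
  shortest-duration peak;
* recovery: `y(t) = y∞ − A1·exp(−t/τ1)` (mono) or
  `y∞ − A1·exp(−t/τ1) − A2·exp(−t/τ2)` (bi), components ordered τ1 < τ2
  and amplitudes reported as fractions of A1+A2.

Seeding: V50 from linear interpolation at half-maximum; the Boltzmann
slope from the 25–75% transition width divided by 2.2 (a span-based seed
can be an order of magnitude off and lets the optimizer collapse into a
degenerate step); exponential time constants from log-linear regression on
the approach to the final value; bi-exponentials from a two-stage peel-off
(slow component from the late half, fast from the early residual). The
two-parameter normalized Boltzmann (amplitude pinned at 1) is used in the
reproduction pipeline since the normalized equations carry no amplitude;
the general fitters default to a free scale. A bi-exponential fit whose
smaller component carries <1% of the amplitude, or whose time constants
are within a factor of 3, is flagged degenerate rather than reported as a
confident second component.

Time-constant extraction windows: activation, from the segment start to
the current peak; inactivation, from 110% of the time-to-peak to the
segment end (excluding the activation shoulder); deactivation, from the
tail-segment peak to its end.

## Parameter fitting (PSO-GSS)

`navmarkov.fitting` estimates selected rate-law parameters directly from
macroscopic current families. The cost is the sum over protocols of the
sum of squared current residuals, each protocol normalized by its target
family's peak magnitude (equal per-protocol weighting). The optimizer is a
canonical global-best particle swarm (inertia 0.729, cognitive = social =
1.49445), box-bounded, with pre-exponential/saturation factors searched in
log10 space (the packaged rates span five orders of magnitude); every
`gss_every` (default 10) generations the global best is polished by a
bounded golden-section line search along each coordinate. All randomness
flows from one seed; identical seeds give identical reports. Joint
refitting of the full parameter set at publication scale is out of scope —
practical identifiability from a handful of protocol families supports at
most a few free parameters, and the packaged recovery guarantee is for ≤4
free parameters on noiseless model-generated data.

## Synthetic data

The generator overlays i.i.d. additive Gaussian noise, scaled to the trace
family's peak current, on simulator output (optionally with a linear
baseline drift), and produces noisy closed-form Boltzmann/exponential
samples. This emulates broadband recording noise only: no capacitive
transients, series-resistance error, leak, filtering correlation, or
cell-to-cell parameter variability. Tests passing on these fixtures
demonstrate correctness of the analysis chain, not robustness to every
artifact of real recordings.

## Numerical choices

* Row-sum and detailed-balance checks: relative 1e-10.
* Stationary distributions: least squares on Q augmented with the
  normalization row; residual above 1e-8 (relative to the largest rate) or
  negative components raise instead of returning a spurious vector.
* Occupancies are clipped at 0 and renormalized each segment; drift is
  below 1e-9 per segment for both propagators.
* Boltzmann slope lower bound: 2% of the fitted voltage span.
* Degenerate inputs (empty sweep lists, non-monotone sweep values,
  zero prepulse peaks, fits at a segment boundary) raise with diagnostics
  naming the offending segment or quantity.

## Known limitations

* **Ladder-square circulation.** The published parameter set fixes the
  availability midpoint near −89 mV with slope ≈5.5 mV, and (through the
  recovery time constants) the recovery exits φ1/φ2. Requiring detailed
  balance on the closed↔inactivated squares then forces the derived
  mid-column entry rates to grow like φ2/φ1 with depolarization, which
  suppresses the G–V foot and pushes the simulated activation midpoint
  several millivolts left of its published value — we verified numerically
  that no fully balanced variant reproduces all the published
  characteristics at once. The shipped wiring therefore balances the outer
  ring (closing the derived deactivation rate) and all four slow-row
  squares exactly, while the three closed↔inactivated squares carry a
  small stationary circulation — a property shared by many published Nav
  gating models. Consequence: at a constant holding potential the model's
  stationary state is a non-equilibrium steady state with a weak
  probability current around those squares.
* **α3 is packaged but unused.** Every tested placement of the α3 law
  either breaks one of the published characteristics or requires extreme
  scale powers; the reproduced quantities are insensitive to its true
  position, so the default wiring omits it rather than guessing. Custom
  scheme files may reference it freely.
* **Hyperpolarized deactivation tails are too fast.** The balance-derived
  O→C3 rate grows steeply with hyperpolarization (microseconds-scale tails
  below −80 mV). None of the reproduced quantities depends on it — tail
  decay at physiological deactivation voltages (−40…−30 mV) is in the
  plausible sub-millisecond range — but simulated deactivation families
  should not be over-interpreted at strongly negative tail voltages.
* The simulated G–V slope factor (≈10 mV) is steeper-footed/shallower-
  topped than the measured 7.2 mV; only the midpoint was constrained.
* Macroscopic mean currents only (no single-channel stochastic
  simulation), ideal clamp, no temperature correction (parameters are for
  23–25 °C).
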