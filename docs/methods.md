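# Methods

## Model

`sigspec` models two signaling pathways sharing an intermediate component as
mass-action production/decay ODEs for the *active* species only; inactive
precursors are not tracked, so activation appears as zeroth-order production
modulated by the upstream signal. One model component may stand for a whole
conglomerate (e.g. a receptor complex plus upstream steps), which is why the
rate coefficients are phenomenological. All units are arbitrary but
consistent; concentrations and times are dimensionless in practice.

Inputs are exclusive by design: a network is evaluated under X input
(`x0 > 0, y0 = 0`) or Y input (`x0 = 0, y0 > 0`), never both. Simultaneous
stimulation and time-varying input programs are out of scope — every claim
here is about steady states, and some (notably the impossibility of mutual
fidelity without cross regulation) are *only* true at steady state.

### Architectures

* **basic** — shared `x1` drives both outputs; no insulation.
* **cpi** — `y2` production multiplied by `1/(1 + x2/eps_g)`; `eps_g` is the
  IC50, the amount of `x2` giving 50% inhibition. Affects only Y outputs.
* **cs** — `x2` production multiplied by a coincidence gate: 1 under X
  input, `k_leak ∈ [0, 1]` under Y input. The third receptor is not modeled
  as a dynamic species; the gate is exactly its normalized flux. Affects
  only the X crosstalk term, scaling it by exactly `k_leak`.
* **sc** — `x1` exists in two exchanging pools (scaffold-anchored `x1N`
  feeding `x2`, cytosolic `x1C` feeding `y2`), exchange rates
  `D_in`/`D_out`. The printed output equations of this architecture carry
  unit production prefactors; we keep explicit `a2`/`b2` defaulting to 1 so
  the conventional form is the default while the general case stays
  expressible.

### Activation

`linear` (identity; the weakly-activated limit), `hill`
(`u^n/(u^n + eps^n)`, half-max exactly at the threshold), or `custom` (any
monotone non-decreasing callable — used by the property tests that only
assume monotonicity). Hill exponents are treated as continuous reals
throughout; exponent 1 is hyperbolic/Michaelian, larger is ultrasensitive.
The canonical diagnostic is the input fold-change for a 10%→90% output
rise, `81^(1/n)`.

## Steady states

Every architecture has a closed-form fixed point: `x1` (or the 2×2 linear
pool system for sc) resolves first, the outputs follow through the
activation functions, and for cpi the inhibition factor uses the
already-resolved `x2` (the inhibition is one-directional, so no implicit
equation arises). The analytic solver is the production path.

The numerical solver integrates the ODEs from the all-zero state (active
species start unformed) with LSODA, in chunks of 50 slowest-relaxation
times, doubling the horizon until `‖rhs‖∞ < tol·(1 + ‖state‖∞)` with
default `tol = 1e-10` and `t_max = 1e6`; non-convergence raises rather than
truncating. Because closed forms exist, the integrator serves as an
independent oracle — the suite checks agreement to 1e-6 relative error on
500 randomized instances, and in practice agreement is ~1e-11.

## Indicators

Ratios follow extended-real conventions: positive-over-zero is `+inf`
(a pathway with zero spillover has perfect specificity — the `D → 0` sc
limit), `0/0` raises, and minima over values including `+inf` are ordinary
extended-real minima. Unnormalized indicators are the default; diagonal
normalization (each output rescaled by its cognate response, making
`S_X ≡ F_Y` and `S_Y ≡ F_X`) is an explicit opt-in, since the right
characteristic concentration is system-specific. Normalization by basal
activity is not implemented.

## Bounds

At fixed CRT the maximal MFMS is: 1 (cpi/linear), `sqrt(CRT)` (cs/linear),
`1 + CRT` (sc/linear, attained; and cpi/ultrasensitive, approached),
`CRT` (cs/ultrasensitive, approached), and for sc with `n = m` the ceiling
`(1 + CRT)^n`, with the symmetric network attaining an exact closed form
(see `bounds.sc_symmetric_mfms`). Two of these required a decision:

* **cs/linear.** The four indicators reduce to
  `min{r, CRT/r, s·CRT, 1/s}` with `r = alpha/beta` and `s = x1|X / x1|Y`.
  Each pair is maximized at its geometric mean, giving `sqrt(CRT)` at
  `r = sqrt(CRT)`, `s = 1/sqrt(CRT)`. We verified this against brute-force
  optimization of the full network before adopting the closed form.
* **sc/ultrasensitive, asymmetric.** For `n = m`,
  `min(F_X, F_Y) ≤ sqrt(F_X·F_Y) ≤ (1+CRT)^n` because a Hill function's
  logarithmic derivative is at most `n/u`, so `f(ru)/f(u) ≤ r^n`; the pool
  ratios contribute `(u/v)(1+CRT)` and `(v/u)(1+CRT)` whose product is
  `(1+CRT)^2`. This ceiling equals the `a → 0` limit of the symmetric
  closed form, so it is tight.

The symmetric-sc reduction is pinned to `d1x = d1y = 1`,
`D_in = D_out = 1/CRT`, `a1·x0 = b1·y0 = a`, `alpha = beta = 1`,
`eps_X = eps_Y = 1`: the unique scaling under which the anchored pool under
X input equals `a(1+CRT)/(2+CRT)` and the closed form is exact.

## Derivative-sign analysis

Whether raising an exponent helps is decided by the sign of the indicator's
partial derivative, computed by central finite differences on the
closed-form indicators with step `max(1e-4, 1e-4·n)`, confirmed under step
halving (the finer step wins on disagreement); magnitudes below `1e-7`
relative resolution report as `zero`. Only signs are interpreted — the
magnitudes of these derivatives are not meaningful model outputs. The
specificity signs are cross-checked against their threshold closed forms
(shared-component steady state vs threshold, per pool for sc); the fidelity
signs depend on both steady states jointly and carry no clean threshold
form, so they are checked for sign-stability only.

Mutual-benefit feasibility (can raising *both* exponents help?) is an exact
interval check: always infeasible for single-pool architectures (the
threshold conditions chain cyclically), and for sc feasible exactly when
`x1N|Y < eps_X < x1N|X` and `x1C|X < eps_Y < x1C|Y`, with the intervals
returned as witness.

## Randomized ensembles

The sweep engine is the package's synthetic-data generator: it emulates a
Monte-Carlo survey of what each mechanism achieves over a broad but
biologically moderate parameter range, not any particular organism's
measured rates. Decay rates and inputs are fixed at 1, so sampled `a1`,
`b1` are the ratios `a1/d1`, `b1/d1` and sampled `a2`, `b2` are the
connection strengths `alpha`, `beta`. Default ranges per mechanism:

| mechanism | a1/d1    | b1/d1    | alpha    | beta     | eps_Y      |
|-----------|----------|----------|----------|----------|------------|
| cpi       | [1, 5]   | [0.1, 1] | [0.1, 5] | [0.1, 5] | [0.01, 10] |
| cs        | [0.1, 1] | [1, 5]   | [0.1, 5] | [0.1, 5] | [0.01, 10] |
| sc        | [1, 5]   | [1, 5]   | [0.1, 5] | [0.1, 5] | [0.01, 10] |

`eps_X` is fixed at 1, setting the concentration scale. Ratios are sampled
uniformly on a linear scale; `eps_Y` log-uniformly, since its range spans
three decades (both laws are configurable — no canonical sampling law
exists for such surveys). The CRT is pinned during exponent sweeps (default
10, i.e. constant and high enough not to be the limiting factor); `crt=None`
samples it log-uniformly over [0.01, 100]. Draws are keyed on
`(seed, draw_index)` and reused across the exponent grid, which pairs the
curves and reduces Monte-Carlo noise. Percentiles are nearest-rank with
`+inf` above all finite values.

Default ensemble sizes: 10,000 trials for distribution maxima, 1,000 trials
per exponent for percentile curves — at 1,000 trials the 90th-percentile
curves are stable to a few percent across seeds, which is sufficient for
the qualitative shape comparisons the tests make.

What these ensembles do *not* emulate: molecular noise, enzyme saturation
in the shared tier, retroactivity, parameter correlations, or time-varying
inputs. Passing sweep tests therefore says the *steady-state architecture
comparison* behaves as derived, not that any real pathway's numbers are
predicted.

## Constrained maximization

`maximize_mfms` probes bound sharpness: seeded differential evolution
(popsize 16, full iteration budget, Sobol initialization, final local
polish) over log10-scaled free parameters spanning ±2 decades, exponents
searched continuously in [1, 10] unless pinned. The search is statistical,
not a global-optimality proof; in practice it reaches every known ceiling
to machine precision. Strict theoretical bounds (e.g. `1 + CRT` for
ultrasensitive cpi) are *attained* numerically because Hill saturation
rounds to exactly 0 and 1 in floating point; bound-compliance checks
therefore allow equality.

## Degenerate inputs and tie-breaks

* `k_leak = 0` (cs) and `D = 0` (sc) give infinite CRT and zero crosstalk;
  indicators become `+inf` rather than erroring.
* A quartet with a zero cognate *and* zero crosstalk output raises
  `UndefinedIndicatorError`; sweeps drop and count such draws.
* `x1` exactly at a threshold reports a `zero` derivative sign, the honest
  boundary answer.
* cs under simultaneous positive inputs is undefined and raises.

## Known limitations

* Steady-state only; no transient or stochastic behavior.
* One-directional insulation only (cpi inhibits Y only; cs gates X only);
  bi-directional or stacked mechanisms are not modeled.
* The sc exchange model assumes first-order pool exchange; scaffold
  titration and combinatorial scaffold occupancy are not represented.
* Bound sharpness for the ultrasensitive cases rests on numerical search,
  not symbolic proof.
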