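# Methods

## Models and assumptions

Two impulsive predator–prey families are implemented. Both are
piecewise-smooth: between impulse times the state follows an ODE; at
impulse times it jumps. Solutions carry left and right limits at every
jump, and all densities are non-negative by construction.

**Release-only Lotka–Volterra system.** Two competing prey (the pest
classes) and one predator, with a periodic predator release of size `p`
every `T` time units. The historically printed form of this system has two
oddities: the second prey equation carries an `x1` leading factor, and the
predator conversion term for prey 1 enters negatively. Both are almost
certainly typographical (the first lets prey 2 grow without any prey 2
present; the second makes kills starve the predator), so the default is
the standard competition form — leading factor `x2`, conversion signs
(+, +) — with `x2_growth_mode="as_printed"` and
`conversion_sign_mode="as_printed"` reproducing the literal text for
comparison. Under the default, every per-capita equation carries its own
state as a factor, which is what preserves non-negativity.

**Stage-structured pest with pulsed births.** The continuous part has no
reproduction: immature prey die (`death_immature`), mature
(`maturation`), and are predated (`r1`); mature prey die (`death_mature`)
and are predated (`r2`); the predator dies (`b3`) and converts kills into
births (`d`). All reproduction enters the immature class at impulse times
through the joint birth-pulse/pesticide map

    x1(t+) = (x1 + Σ_k π_k B_k(x1, x2)) (1 − E),

evaluated entirely at the pre-impulse state: births and spraying form one
simultaneous map, not a birth step followed by a spray step. By default
the pesticide touches only the immature class; `kill_mature` /
`kill_predator` optionally scale `x2` / `y` by `1 − E` as well (off by
default, since the canonical map acts on the immature class alone).

**Birth pulses.** Beverton–Holt `b·x2/(q + x1 + x2)` (saturating in total
density, half-saturation `q`) and Ricker `b·x2·exp(−(x1 + x2))`. The
Ricker damping uses total density `x1 + x2`, matching the Beverton–Holt
denominator's density dependence. A pulse mixture is a convex combination
with weights summing to 1 within 1e−12.

**Impulse scheduling.** Events with a positive phase offset fire at
`nT + offset` for `n = 0, …`; offset-0 events fire at period boundaries
`T, 2T, …` ("impulse at t = nT, n a positive integer"). When a birth/
pesticide event and a predator release share an offset, they are applied
in listed order; the fixtures list the birth/pesticide event first, then
the release — the relative order of the release is a free choice and is
configurable through the event list.

## Numerical integration

Impulse times are known a priori, so the integrator uses *hard
segmentation*: integrate the smooth field to the next event time
(computed by multiplication `n*T + offset`, never by accumulating step
sizes), apply the map, restart. No event-detection root finding — runs
are bit-reproducible. Segments use `scipy.integrate.solve_ivp` (RK45
default; DOP853/LSODA/Radau/BDF selectable) with default tolerances
rtol = 1e−8, atol = 1e−10.

After every segment and impulse, components with magnitude below 1e−13 —
and small negative excursions up to 100·atol, which adaptive steppers can
produce when a density collapses to zero — are snapped to exactly 0; a
negative component beyond that bound raises an error rather than being
hidden. This keeps the multiplicative fields from amplifying spurious
negatives during eradication runs where densities pass through 1e−30.

**Compiled fast path.** The weight-selection experiment evaluates the
"does efficacy E eradicate?" predicate tens of thousands of times. That
predicate (and only it) has a numba-compiled implementation: an adaptive
Dormand–Prince 5(4) stepper with the standard embedded-pair error control
plus the impulse maps and the windowed eradication test. The scipy-based
path remains the reference; the test suite checks that the two agree on
eradication outcomes across an efficacy grid and that the compiled E*
matches the reference E* exactly at the bisection resolution. Non-RK45
methods always use the scipy path.

## Eradication, operationalized

The underlying theory defines eradication as the pest tending to zero;
no finite simulation can verify a limit, so the package uses a numeric
surrogate: a scenario is *eradicated* when the maximum total prey density
over the final `window` periods stays below `epsilon`. Defaults:
epsilon = 1e−6 (density), window = 50 periods, horizon = 500 periods.
Fixtures use scaled-down horizons (stage mixture: 80/10; stochastic
sweep: 60/8 with epsilon = 1e−5; baseline: 400/20) chosen so the decision
is reached well inside the horizon at the fixtures' decay rates. The
indicator exits early on success (a full window already below epsilon) or
on escape (prey exceeding 1e4 × its initial scale).

**Critical efficacy E\*.** Bisection on E ∈ [0, 1] at tolerance 1e−3 —
E is a fraction, so finer precision would exceed modeling fidelity.
Monotonicity of eradication in E is assumed after an endpoint check
rather than proven: E = 1 is tested first; if it fails, E = 0 is tested,
and success there raises a non-monotonicity error (such scenarios exist,
e.g. a pesticide configured to harm only the predator). If E = 1 fails
and E = 0 fails, the result is E* = 1 flagged unconverged. The E = 0
endpoint is otherwise tested only when the bracket collapses onto it,
saving one full-horizon simulation per Monte-Carlo draw without changing
the result contract.

**Thresholds.** The pest-free orbit, its period average `p/(b3·T)`, the
invasion exponents `λ_i = b_i T − r_i p/b3` and the critical release
`max_i b_i b3 T / r_i` are closed forms derived from the pest-free
subsystem; simulations cross-check them in the test suite.

## The stochastic experiment

Stochasticity enters through the pulse magnitude b (the "birth rate"
random variable); shape constants q are fixed per scenario. Priors:
uniform (non-informative over a range), exponential (small pulses
prevalent, large ones rare), point (degenerate; useful as a control).
Three average-birth-rate levels — low, medium, high — use prior means
0.5, 2 and 5 in scaled density units; these are illustrative scales, not
field-calibrated values (no canonical values exist).

By default one shared draw feeds both mixture components ("the"
birth-pulse parameter is a single random quantity); per-component
independent draws are available (`share_draws=false`), with one
independent substream per component spawned from the same seed so adding
a component never perturbs the others.

For each candidate π on a finite grid (default {0, 0.25, 0.5, 0.75, 1};
the endpoints are included as diagnostic single-pulse cases), the engine
computes E* per draw under common random numbers and scores π by the
dispersion of the E* sample: unbiased sample variance by default, sample
SD or coefficient of variation selectable — "variation of E" has no
canonical definition, so the measure is a config choice. Draws whose
bisection cannot converge (E = 1 fails within the horizon) enter the
sample as E* = 1 and are flagged; they are included in the dispersion by
default (penalizing near-infeasible scenarios), excludable by config.
π* is the argmin; ties break toward the smallest π. A grid search rather
than continuous optimization keeps the experiment reproducible and the
full per-candidate sample inspectable; the grid is configurable.

All randomness flows from one top-level seed. The CLI's `optimize-pi`
derives one named substream per prior setting (a hash of seed and the
setting label), so results for one setting are stable under adding or
removing other settings.

## What the fixtures emulate — and what they do not

The synthetic scenarios reproduce the *structure* of the study
conditions: a release-only system parameterized exactly at its
eradication boundary; a stage-structured two-component Beverton–Holt
mixture (q = 0.5 vs q = 5, i.e. a weakly vs strongly saturating pulse)
with joint pesticide and release; and the full 3-level × 2-prior × π-grid
sweep at 50 draws per candidate. Parameter values are plausible scaled
units, not calibrated to any organism; passing tests therefore
demonstrate correctness of the machinery (thresholds, bisection,
common-random-number coupling, reproducibility), not predictions about a
real pest. Real systems also feature measurement noise, non-periodic
interventions and density dependence in forms not modeled here.

## Known limitations

- Eradication is a finite-horizon surrogate; scenarios whose E* sits in a
  region of very slow dynamics can be classified conservatively (E* is
  then an upper bracket at the configured horizon). Bisection and grid
  search share the same indicator, so they remain mutually consistent.
- No formal Floquet/monodromy analysis of the full 3-D system; the
  invasion exponents are one-species linearizations about the pest-free
  orbit.
- State-dependent (economic-threshold-triggered) impulses, disease
  compartments and nonlinear functional responses (Holling II,
  Beddington–DeAngelis, Ivlev) are out of scope.
- The coefficient-of-variation dispersion is undefined at mean 0 and is
  reported as infinite there.
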