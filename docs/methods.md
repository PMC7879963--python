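# Methods

## Model structure and assumptions

The simulator is an aggregate (non-stochastic, non-agent) stock-flow model
advanced annually from 2010 through 2060 — 51 recorded states. Stocks are
measured at January 1 of each year; flows are rates in persons/year that act
over the following year. Integration is forward Euler with Δt = 1: all
flows are evaluated simultaneously from the prior year's state, so results
never depend on the order in which flows are declared. The final recorded
year's flows are evaluated (and reported) but the resulting state falls
outside the horizon.

Flow rates are small arithmetic expressions (`+ − * /`, parentheses,
numeric literals, parameter and stock names) parsed once at load time
against a strict whitelist; a model specification can therefore be fully
declarative (YAML with `stocks`, `flows`, `parameters` sections) without
ever executing arbitrary code. Parameters may be scalars or per-year paths.

Negative stock levels are never produced: an overdrawn compartment is
clamped at zero and the deficit is logged on the trajectory. Clamping is
deliberately *not* hidden by redistributing the shortfall — a nonzero clamp
log is a visible mass-balance diagnostic, and the shipped parameterization
runs with a clamp total of exactly zero.

The population is split into adults with no prior CVD event (`non_cvd`) and
adults with at least one (`post_cvd`). Transfers between the compartments
happen only through survived first CVD events; deaths leave the system; a
net aging/in-migration inflow enters `non_cvd`. Post-CVD severity is encoded
as rate ratios ≥ 1 applied to the non-CVD event, fatality and mortality
rates. Closed sub-systems conserve persons to floating-point accuracy, and
the integrated model satisfies Δ(non_cvd + post_cvd) = inflow − deaths each
year to 1e−9 relative tolerance.

## Risk factors and attribution

Twelve risk-factor prevalences follow clipped linear paths
p(t) = clip(p₀ + β·(t − 2010), 0, 1). Mutually exclusive categories of one
factor (current/former smoker, high/borderline blood pressure and
cholesterol, diabetes/prediabetes) are tracked as separate strata whose
prevalences must sum to ≤ 1. Youth obesity has no direct risk link; its
excess over the reference path ages into adult obesity through a carried
stock with an annual transfer fraction (default 0.03/yr) and turnover
(0.04/yr), giving a steady-state pass-through of 0.75.

Event rates combine factors multiplicatively with population-average
normalization: rate = base · Π_i [1 + p_i(RR_i−1)] / [1 + p̄_i(RR_i−1)],
where the reference prevalences p̄ are fixed constants (not tied to the
current parameter values, so sensitivity runs on a prevalence do perturb
the rate). The combination assumes independent risks; no joint-exposure
interactions are modelled. Rates are monotone non-decreasing in each
prevalence whenever RR ≥ 1.

Risk-factor-linked non-CVD outcomes (deaths, hospitalizations, disability)
are *accounting overlays*: attributed count = baseline annual total ×
Levin attributable fraction p(RR−1)/(1+p(RR−1)). Protective exposures
(RR < 1) are rejected for attribution. Scenario mortality differencing uses
the flow-based death series only, so attributed series never double-count.

Each reported measure carries a calibration multiplier (default 1) applied
at the output-reporting layer of that measure alone. Placing multipliers
there, rather than inside the shared dynamics, is what makes recalibration
of one measure provably inert for every other series — an invariant the
test suite checks bit-for-bit.

## Quality-of-care coupling

The quality acute/rehabilitation care lever sets an uptake fraction u ∈
[0,1]; case fatality is scaled by 1 − u·r·e, where e is the care effect
size (default 0.665, plausible range 0.43–0.90) and r = 0.04 is the reach
of upgraded care. The reach value is a fixture design choice sized so the
care effect's wide plausible range produces a few-percent — and the
largest — influence in the sensitivity sweep while no single parameter
dominates the model.

## Levers and scenarios

Levers respond linearly: parameter' = parameter + movement × max_effect,
movement ∈ [0,1], constant over the horizon (no ramp-in; ramps would be a
config extension). Movement 0 is the exact identity. Every shipped lever
satisfies a "no change or better" guard: moving it alone never increases
cumulative deaths, verified by a movement sweep. Price policies translate
into pricing-lever movements as price_change × consumption_share.

Scenario deltas are cumulative sums over a closed outcome window (default
2018–2040, 23 years): deaths/events averted as base − intervention, costs
as intervention − base.

## Economics

Discounting is end-of-year at a default 3%/yr: a cash flow in the base year
has exponent 0, one k years later is divided by (1+rate)^k. Present value
at rate 0 is exactly the plain sum, and PV is linear in the cash-flow
series. Implementation costs are per-lever annual streams proportional to
movement over the outcome window. Medical cost changes are attributable-
fraction costed: Σ_class unit_cost × (scenario count − base count), so
savings enter negative; net cost adds the implementation PV. All ledger
entries carry an explicit cost base year (default 2012); mismatched years
raise rather than silently convert — currency-year conversion is out of
scope. Cost per death averted divides net cost by deaths averted, returns a
NaN sentinel (never divides) when none are averted, and the reporting
helper rounds to the nearest $10,000, half up.

## One-way sensitivity analysis

Each of the 86 shipped parameter bounds is run alone at its low and high
value, all other parameters at defaults, against a single shared base run
(computed exactly once); the focal outcome is cumulative deaths averted by
the all-levers-max scenario. Relative changes use the base-run value as
denominator. Influence = max(|low change|, |high change|); the tornado set
keeps records with influence ≥ 0.5% (inclusive), sorted descending with
alphabetical tie-breaks. A failing bound run yields a flagged record and
the sweep continues, keeping large sweeps restartable and auditable.

Bound bands follow provenance: surveillance-derived rates ±5%, survey
prevalences ±10%, literature relative risks ±10% of the excess (RR−1),
soft couplings ±30–50%, cost entries ±20%; the care-effect bound pair
(0.43, 0.90) is used verbatim. With these bands the fixture exhibits the
regression property that no single parameter moves the outcome by more
than 5% (measured maximum ≈ 4.4%). Cost-side parameters have, correctly,
zero influence on the mortality outcome.

## External validation and recalibration

Model series are compared with observed series on overlapping years (at
least 3 required). "Substantial deviation" is an explicit two-part rule,
logged in every report because the underlying judgment call must be
reproducible: a measure deviates iff MAPE > 10%, or the OLS trend slopes of
model and observations have opposite signs with both magnitudes above a
noise floor (default: the observed slope's standard error). MAPE is
relative, so percent and count measures are treated identically and the
diagnostic is invariant under uniform rescaling of both series.

Recalibration fits the measure's multiplier by least squares on relative
error: in constant mode the closed-form minimizer m = Σa / Σa²
(a = model/observed); in linear-trend mode log(observed/model) is regressed
on year and the fitted log-linear path is extended over the whole clock.
Both modes are provided because either a level offset or a trend divergence
can be the real failure mode. Noise-free planted multipliers are recovered
to 1e−6; at 2% relative noise, to within 5%.

The anti-over-calibration guard: only measures that are deviating *and*
persistently one-sided (residual sign constant over ≥ 3 consecutive
observation points) are recalibrated. Transient oscillation around the
model — however large its MAPE — is excluded. In the shipped panel this
distinguishes the four persistent planted deviators from the three planted
transient wobbles at every seed tested.

## The synthetic surveillance panel

The fixture emulates the *shape* of national surveillance: biennial survey
points (2011, 2013, 2015) for prevalence and disability measures, annual
2010–2016 series for death/hospitalization counts and the post-CVD
interview measures. Observations are model output × planted multiplier ×
lognormal noise (relative sd 0.02, mean-one). Four measures carry
persistent plants (constant 1.3 on adult obesity and CVD deaths; a 5%/yr
log-linear drift on diabetes- and distress-related non-CVD deaths — the
smallest round drift that is detectable by the deviation rule over a
seven-year window); three carry an alternating ±15% wobble. The noise
stream is spawned per measure from the seed, so changing the seed changes
the noise but never the plants.

What the fixture does **not** emulate: survey weighting and clustering,
age/sex/race stratification, measurement error structure, reporting lags,
or any real national estimates — all numeric values are openly fictitious.
Passing tests therefore demonstrate that the *machinery* (conservation,
attribution, sweep, deviation flagging, recovery, cross-effect isolation)
is correct, not that the toy nation forecasts any real population.

## Problem sizes and runtime

Default runs use 1,000,000 adults, 51 annual steps, 25 reported measures,
6 levers, 86 sensitivity bounds (173 scenario runs per sweep) and a
25-series panel. The complete generation + base run + sweep + validation +
recalibration cycle takes a few seconds on one CPU; the test suite runs in
well under a minute.

## Numerical conventions and edge cases

- All model arithmetic is deterministic float64; identical inputs give
  bit-identical trajectories (no RNG anywhere in the dynamics).
- Ties in tornado ordering break alphabetically; threshold comparisons are
  inclusive (≥).
- A zero base outcome flags the sensitivity record rather than dividing.
- Zero observations are rejected before MAPE; fitted multipliers must be
  strictly positive.
- Division by zero or a non-finite rate in a flow raises a numeric error
  naming the flow and year; unknown expression symbols are specification
  errors naming the symbol.
- CLI artifacts are byte-identical across reruns with the same seed; the
  run manifest hashes them (its own timestamp field differs between runs).

## Known limitations

No age/sex/race structure, no sub-annual dynamics, no stochastic or
agent-based variants, no infectious disease, no QALYs or indirect costs,
no currency-year conversion, and no claim of numeric agreement with any
production policy model — this package is a transparent member of the same
model class with its validation harness built in.
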