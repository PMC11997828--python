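# Methods

## Scope and perspective

The package implements a trial-based benefit–cost analysis from the provider
(trial) perspective: incremental costs are the delivery costs of the
intervention packages themselves, because both arms use the public
healthcare system equally and that utilization cancels in
`(interventions + routine care) − routine care`. No routine-care cost input
is therefore required (or accepted). All money is carried at full precision
internally; rounding to one decimal happens only at the reporting boundary
(`round_report`, half away from zero, matching how such results tables are
printed).

## Sign conventions

Effect sizes are stored as true absolute risk reductions: positive = fewer
adverse events, in percentage points. Published effect tables often print
the raw risk difference (intervention − control), where a *negative* number
is a benefit; the packaged fixture flips those signs on transcription, and
confidence intervals are orientation-normalized on ingest so
`ci_low ≤ point ≤ ci_high` always holds. Mean differences (cognition) pass
through as printed, positive = improvement. All valuations are linear in
the effect, so a harmful point estimate simply produces a negative monetary
benefit; negative totals yield a negative (reported, never clamped) BCR.

## Valuation channels and discounting

- **Mortality**: `(ARR/100) × VSL`, with `VSL = gni_pc_ppp × vsl_ratio`
  (default ratio 100, income elasticity 1, no age adjustment). Deaths and
  stillbirths fall inside the 0–2-year trial window, so no discounting is
  applied by default; `EconParams.discount_mortality` applies a one-year
  midpoint factor for scenario work.
- **Morbidity**: `(ARR/100) × DW × T1 × VSLY`, i.e. averted YLD valued at
  one VSLY (`VSL/35`) per DALY. `T1` is the persistence of the condition in
  years and may be fractional (1.5 y for conditions spanning preconception
  plus pregnancy; 2 y for chronic conditions such as depression and
  hypothyroidism). Persistence is undiscounted by default — the published
  per-outcome benefit cells this package is calibrated against only
  reproduce that way — and `EconParams.discount_morbidity` switches on an
  annual-plus-fractional-tail discounted annuity (`persistence_factor`).
- **Productivity**: `w × f × effect × Σ_{t=a}^{a+W−1} y₀(1+g)^t(1+r)^−t`,
  with overlap weight `w = 0.6`, working years `W = 35` from earnings start
  age `a = 18`, and baseline earnings `y₀` defaulting to GNI per capita.
  When `g = r` the stream collapses to `W × y₀` exactly.

Outcomes without a disability weight cannot be routed to the morbidity
channel (validation enforces this); the source analysis likewise excluded
such outcomes. Future healthcare savings can be added as an optional
per-dyad benefit line (`healthcare_savings_per_dyad`, default 0) since no
magnitude was published.

## Costing

Phase unit costs are ingredient ledgers over eight components. Shared items
are apportioned by utilization fraction with *exact* conservation: the
largest share absorbs the floating-point residual, and because bit-exact
reachability of the total can be blocked by round-to-even, the smallest
share is nudged by ulps (≤ a few 1e-16 relative) to shift the rounding
lattice until a plain left-to-right sum of the returned allocations equals
the total bit-for-bit.

The published formula table repeats the preconception term inside group C,
which would make groups C and A identical; the published per-dyad costs are
only consistent with group C *excluding* that term, so the corrected form is
the default and the printed form sits behind
`include_preconception_in_group_c`. Cost-side discounting is available via
per-phase timing offsets but defaults to none: the published per-dyad costs
reproduce without relative discounting across the 4-year delivery window.
Children who died are costed to their average age at death via an optional
early-childhood exposure weight (default 1).

## Calibration of the packaged fixture

The source trial's supplement (disability weights, persistence horizons,
GNI, productivity coefficients, sensitivity ranges) is not available, so the
fixture carries calibrated values, documented as such and editable:

- GNI per capita PPP 7130: the VSL back-solved from all three published
  mortality benefit cells is exactly 713 000 $PPP at ratio 100.
- Disability weights: GBD-2019 values where they fit exactly (anaemia
  0.004/0.052/0.149 by severity, depression 0.396, hypothyroidism 0.019,
  RTI/STI 0.034) with `T1` 1.5 y or 2 y; pre-eclampsia (0.232, 1.5 y) and
  postpartum haemorrhage (0.1141, 1 y) are back-solved.
- Productivity fractions back-solved per pathway assuming `y₀ = GNI` and
  `g = r` (low birth weight 0.1334, stunting 0.1942, wasting 0.0879,
  cognition 0.0559 per SD).

This calibration reproduces every published per-outcome benefit cell at one
decimal in all three comparisons. It also localises a misprint: the
published wasting cell for the pregnancy/early-childhood column (3502.9) is
inconsistent with the wasting multiplier implied by the other two columns,
which gives 502.9 — restoring that column's sum to its published total
(≈28 843.9). The fixture carries the consistent parameters; the published
column *total* remains the authority for that comparison's BCR/NMB. A
green calibrated test establishes internal consistency of the published
table plus our equations, not independent reproduction of the supplement.
Tolerances on cost checks (±0.2 $PPP per dyad) reflect that printed unit
costs are rounded to one decimal and scaled by the dyad ratio ≈2.87.

## Synthetic trial generator

The generator emulates: 1:1 randomisation at enrolment (exact balanced
halves), pregnancy confirmation at rate 2460/6722 ≈ 0.366, a second 1:1
randomisation among pregnant women, child follow-up to 24 months at
2344/2460 ≈ 0.953, Bernoulli binary outcomes at `control risk − ARR/100`
per group, Normal continuous outcomes, phase-wise cost accrual, and
missingness by measurement window (pregnancy outcomes only for pregnant
women, childhood outcomes only for followed children). It does **not**
emulate outcome correlation (valuation is additive, so independence
suffices for pipeline testing), household/twin clustering, compliance,
visit schedules, or covariate structure — crude (unadjusted) ARR/MD
estimates with Wald/Welch CIs are the estimator, so recovery tests verify
the pipeline, not covariate-adjusted inference. Control-arm risks for the
fixture-calibrated world are stated-world choices (not published) sized so
every configured ARR leaves a valid risk.

The end-to-end recovery world used in acceptance testing is designed by a
delta-method power budget: at n = 50 000 women, children number only ~n/11
per group, so a VSL-scale mortality channel would contribute ~1–2 BCR units
of Monte-Carlo noise. The recovery world therefore concentrates benefit in
a high-prevalence maternal morbidity outcome (σ_rel ≈ 2%), keeping the 5%
recovery criterion a ~2.5σ event rather than a coin flip; the
fixture-calibrated world (which *does* carry the mortality channel) is
instead checked against its truth-implied BCRs within 3 delta-method
standard errors. CI-coverage simulation is scaled to 400 replicates of
n = 2500 to stay inside test-suite runtime; at that size the Wald interval's
small-sample bias is still negligible against the ±1.5-point band.

## Numerical choices

- `discounted_stream` sums terms directly; the property suite checks it
  against the `log1p/expm1`-stabilised geometric closed form to 1e-9
  relative over r ∈ (0, 0.2], T ≤ 200.
- Tornado rows re-run the full pipeline with exactly one parameter swapped;
  each row's base BCR must equal the base-case BCR bit-identically (a
  mismatch raises). Rows orient so the low case worsens BCR, sort by
  descending range, and break ties alphabetically for determinism.
- Default sensitivity ranges for VSL, VSLY, growth and cost scale are
  placeholders (±50%, ±2 pp, ×0.5–×2) because the study's exact low/best
  values were not published; effect-size ranges are the multiplicity-
  adjusted 98.3% CI endpoints, which *were* published.
- VSL and VSLY vary independently in sensitivity scenarios: overriding VSLY
  suspends its derivation from VSL for that scenario only.

## Known limitations

- The full valuation chain is calibrated, not independently sourced; users
  with access to the original supplement should replace the fixture values.
- No probabilistic (multi-way) sensitivity analysis, ICER/CEA league
  tables, equity weighting, or societal-perspective costing.
- Per-dyad benefits assume the trial's dyad accounting; population-level
  totals require multiplying by the participant flow externally.
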