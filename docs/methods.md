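# Methods

## Model and conventions

The kill fraction compares a treated subject's growth-normalized volume
to the control group's:

    f_kill(t) = 1 − [V_i(t)/V_i(t0)] / [V_C(t)/V_C(t0)].

Conventions, each chosen once and used everywhere:

- **Control reference.** V_C is the per-day arithmetic mean of the
  control group, not a paired control animal; the design compares
  groups.  A flag (`--reference-subject`) substitutes a named control
  animal instead.
- **Normalization day.** t0 in the definition above is treatment start
  (day 0).  The *onset* day t₀ of the quadratic law is a separate,
  per-subject quantity fitted from the data.
- **Negative values.** f_kill may be negative (treated outgrowing the
  control).  Negative values are kept in the series — they help locate
  the onset — but are excluded from the quadratic fit, whose derivation
  presumes positive response.
- **Silicon scale.** Si is always absolute mass percent of tissue
  (0.00372 means 0.00372%).  No function converts to fractions; this
  removes the ×100 ambiguity at the source.
- **Group dispersion.** SDs use the n−1 sample convention; a single
  subject reports an absent SD, not 0.

## Quadratic response fit

Per subject, f_kill = θ_f·(t − t₀)² is a zero-intercept regression of
f_kill on x = (t − t₀)² over the points with t > t₀ and f_kill > 0.  The
slope at a fixed onset is closed-form, θ = Σf·x / Σx².  The onset is
optimized by exhaustive search over the integer measurement days of the
series except the last two (at least two points must remain); the
candidate minimizing the residual sum of squares wins, with ties (RSS
equal to within 1e−12 relative) going to the earliest onset — earliest
plausible response, deterministic output.  A negative slope is clipped
to 0 and the fit flagged ineligible.

Statistics, computed only when ≥ 3 positive-response points were used:

- R² = 1 − SSR/SST with SST about the **mean** of the fitted points.
  For zero-intercept models some software takes SST about zero, which
  inflates R²; the about-mean convention is declared here because
  published per-subject R² values computed under an unknown convention
  cannot be recomputed from the printed data anyway (the per-animal
  volumes appear only in supplementary material).
- p-value: the one-degree-of-freedom F-test of the zero-intercept
  quadratic against the zero model, df = (1, n−1).  The original
  analysis does not name its test; this is the closest standard choice.

Subjects with fewer than 3 positive-response points (e.g. response
starting on the penultimate measurement day, leaving two points) are
flagged ineligible and excluded from the cross-subject fit — the rule
that removed two of the seven published animals.  The fitter never
raises on unresponsive subjects; it returns a flagged record.

## Exponential uptake–response fit

θ_f = A·e^{B·Si} is fitted by nonlinear least squares **on the θ scale**,
not on log θ.  The goodness of fit reported for this law (R² about the
mean θ) is defined on that scale, and on the five retained published
pairs only the θ-scale fit reproduces R² = 0.817; least squares on
log θ weights the small-θ subjects far more heavily and lands on a
different curve with a much lower θ-scale R².

The optimizer is a damped Gauss–Newton (Levenberg) iteration with the
analytic Jacobian [e^{B·Si}, A·Si·e^{B·Si}], started at the closed-form
regression of ln θ on Si.  Only improving steps are accepted, so the
solution's RSS never exceeds the initializer's (asserted in tests);
convergence is a relative RSS change below 1e−12, capped at 500
iterations (hitting the cap flags `fit_method`).  No random restarts:
the fit is deterministic given its inputs.  Standard errors for (A, B)
come from the Gauss–Newton normal equations, and `confidence_interval`
builds Wald intervals with the t quantile at n−2 degrees of freedom —
at 3–7 subjects these are wide, which is the honest statement of the
law's small-sample fragility.

On the five retained published pairs this fit gives A ≈ 1.76e−5,
B ≈ 1664.4, R² = 0.8170.  The exponent agrees with the published
B = 1664.39 to four significant figures; the published prefactor
A = 0.000172 is an order of magnitude above the conditional least-squares
value at that exponent, so the two published constants are not jointly
consistent with the published per-mouse pairs under any single Si-unit
convention.  The package therefore reports its own (A, B) and treats the
R² (and B) as the reproducible surface; predictions quoted elsewhere use
the package's own fit.

Predicted kill-fraction curves θ(Si)·(t − t₀)² are capped at 1 with a
flag (a fraction cannot exceed 1).  Validation pools all eligible
subjects' post-onset (observed, predicted) pairs into one vector pair
and reports the Pearson correlation with its t-distributed p-value;
per-subject correlations are kept alongside for transparency, since the
pooling convention behind the published r = 0.89 is not stated.

## Standard additions and %ID

Each tissue sample's GFAA signal is regressed on the added Si
concentration; the native concentration is the x-intercept magnitude
b/m, with SD from the standard x-intercept propagation

    sd = (s_yx/m)·sqrt(1/n + ȳ²/(m²·Σ(x−x̄)²)).

A non-positive slope is a per-sample quantification error; batch runs
emit an error row and continue.  Concentration units are whatever the
additions column declares; nothing assumes µg/mL.

Delivery efficiency uses fixed strain-standard organ reference masses
from configuration (per-animal organ masses are not measured in this
design; the packaged defaults are nominal BALB/c values and should be
overridden where better values exist).  Net Si = measured − control
baseline per organ; nets below baseline are preserved and flagged but
contribute 0 to %ID (physical non-negativity without discarding
information).  %ID = 100 · (net/100 · organ mass) / (si_fraction ·
particle mass per dose · n_doses).  With the packaged constants the
injected Si mass is 0.3936 × 1 mg × 4 = 1.5744 mg.  The published
average tumor delivery efficiency (≈0.22 %ID) depends on per-animal
tumor masses that are not printed, so it is not a quantity this package
can recompute; the %ID math is validated by its linearity/additivity
invariants instead.

## Synthetic cohorts

The generator inverts the analysis chain so every stage is testable
without animal data:

- Controls grow exponentially, V_C(t) = V₀·e^{g·t}.  No control growth
  law is implied by the kill-fraction definition (it cancels); the
  exponential is chosen for realism and closed-form checks.
- Each treated subject draws Si ~ U(si_range), θ = A·e^{B·Si} with
  lognormal spread, and an onset day from a weighted integer-day
  distribution; it follows control kinetics before onset and carries
  kill fraction min(θ·(t−t₀)², 0.99) after.  The 0.99 cap is a generator
  artifact keeping volumes positive, not a model claim.  Multiplicative
  lognormal measurement noise is applied to volumes last.
- GFAA curves are affine signals slope·(c + addition) plus Gaussian
  noise.
- One global seed drives a hierarchical seed tree (cohort → subject), so
  the same seed is bitwise reproducible and per-subject streams are
  independent.

Default study-scale conditions (the `table1_like_cohort` spec): 7 mice
per group; measurement days 0, 3, 7, 8, 9; 500 mm³ at treatment start;
growth rate 0.12/day (≈3-fold over the 9-day course, typical of an
aggressive syngeneic breast tumor); Si ~ U(0.001, 0.006) mass %; uptake
law (A = 6.31e−4, B = 460.5), which maps the Si range onto θ ∈
[0.001, 0.01] per day² — the span of the published coefficients among
responding mice; onset-day weights 0.7/0.15/0.15 on days 0/3/7
(most published animals responded immediately, two only at day 7);
lognormal σ of 0.1 on volumes (caliper-scale error) and 0.2 on θ;
GFAA slope 100 signal units per concentration unit with additive noise
SD 0.005.  These defaults are the study conditions for every recovery
test; they are set once, not tuned per test.

What the generator does **not** emulate: free-drug pharmacokinetics,
immune dynamics, metastasis, inter-organ uptake correlation (none was
observed in the source data), non-exponential control growth, or
heteroscedastic instrument noise.  Passing recovery tests therefore
show that the pipeline inverts its own generative assumptions — not
that real cohorts satisfy them.

## Problem sizes and numerical choices

The test suite runs the oracle-equivalence checks on 1,000 seeded
instances each (quadratic fitter vs. exhaustive grid oracle; standard
additions vs. closed-form OLS) and the noise-level parameter recovery on
200 replicates of 50 subjects; the study-scale coverage check runs 200
replicates at 7 mice/group.  The whole suite completes in a few seconds
on one CPU.  Degenerate inputs are handled explicitly: unresponsive
subjects return flagged fits instead of raising; a constant θ recovers
B ≈ 0; zero-residual fits report R² = 1 and p = 0 exactly; SST = 0 with
nonzero residuals reports R² as NaN rather than a misleading number.

## Known limitations

- Onset days are restricted to actual integer measurement days; onset
  between visits biases θ̂ upward at the next grid day.
- With 5–7 subjects the exponential law's (Â, B̂) are highly variable
  (interval coverage of the generative values is measured at ~90% with
  t-based 95% intervals, and single-seed estimates of B range widely);
  conclusions at study scale rest on the R², not on the point estimates.
- The eligibility filter couples to the onset search: a subject whose
  best-RSS onset leaves two points is excluded even if an earlier,
  slightly worse onset would keep three.
- %ID uses reference organ masses; true per-animal masses would change
  the absolute %ID values proportionally.
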