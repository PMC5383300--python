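# Methods

## The disease model

The arterial wall carries three integer cell counts, all zero at birth:
macrophages M, foam cells plus persistent debris F, and vulnerable plaques
R.  Five first-order rates (per year) govern the dynamics:

| parameter | meaning | default / bounds |
|---|---|---|
| Nν₀ (`nu0N`) | monocyte uptake, pool size × per-cell rate | free in [1, 10] |
| α (`alpha`) | macrophage proliferation | fixed 12 |
| γ (`gamma`) | net proliferation, γ = α − β − ν₁ | free in [0.1, 0.3] |
| ν₁ (`nu1`) | foam-cell formation | free in [0.1, 12] |
| ν₂ (`nu2`) | plaque seeding per foam cell | fixed 10⁻⁷ |
| t_lag | plaque-to-stroke lag (years) | fixed 10 |

γ, not the death/emigration rate β, is stored and fitted: it is the
deviation from homeostasis that the data constrain, and β = α − γ − ν₁ is
always derived.  β < 0 is rejected as an invalid parameterization — the
optimizer sees +∞ deviance there instead of a silently clamped value.  γ
itself may be negative at the type level (it is a *net* rate, and the
α = β = 0 closed-form validation requires γ = −ν₁), but the fit bounds keep
it positive in any cohort analysis.  N and ν₀ are never represented
separately; only their product is identifiable, and for ν₂ ≪ 1/year only
the product ν₁ν₂ is — which is why α and ν₂ are conventionally fixed.

Rates can be modulated three ways, composed in a fixed order (age law →
categorical factors → dose factor; the factors commute, so the order only
matters for error attribution):

* **Age power law** η(a) = η(a₀)·((a+10)/(a₀+10))^ψ with ψ ∈ [−1, 1];
  the 10-year offset regularizes the law at birth.  Reference ages a₀ are
  10 y for Nν₀, 40 y for α, γ, ν₁ and 60 y for ν₂ — the ages at which the
  fit bounds are meant to apply.
* **Categorical covariates** multiply a rate per category (reference
  category pinned to 1).  "Unknown" categories receive their own estimated
  multiplier rather than being merged.
* **Radiation** scales a rate by (1 + λd) (cumulative dose, persistent
  effect) or (1 + λr) (annual dose rate, short-term effect).  A
  non-positive factor is an error, never clamped.

Variables with no biological reading (education, calendar year) do not act
on rates; they enter as multiplicative factors on the hazard — a
reconstruction, clearly so labelled, since only their inclusion, not their
functional form, is derivable from the model's structure.

## Survival and hazard

Cell lineages are independent, so the survival against a first plaque
factorizes over lineages.  Writing v(s,t) = exp(−∫ₛᵗ ν₂) for the
probability that one foam cell present at age s has seeded no plaque by t,
the corresponding probability u(s,t) for one macrophage solves the
backward Riccati equation

    ∂u/∂s = (α+β+ν₁)u − αu² − β − ν₁ v(s,t),   u(t,t) = 1,

and Poisson immigration of monocytes gives
S_R(t) = exp(−∫₀ᵗ Nν₀(s)(1−u(s,t))ds).  Stroke-free survival is
S(a) = S_R(a − t_lag) and the stroke hazard is the first-plaque hazard
shifted by the lag; death from other causes during the lag is handled as
censoring in the likelihood, not inside S.

Numerics.  Rates are piecewise constant on annual age intervals (the
resolution of dose records and the 1-year step used for cohort analysis).
Within intervals a fixed-step RK4 integrator (default step 0.02 y) evolves
u, carrying v analytically; probabilities are validated to lie in (0, 1].
Two paths exist:

* **Homogeneous fast path.**  When the timeline is age-constant, u depends
  only on τ = t − s.  One forward sweep yields S on the whole grid, and
  the hazard is exact: h_R(t) = Nν₀·(1 − u(t)).  This path makes cohort
  fitting cheap (one sweep per stratum and evaluation, ~ms).
* **General path.**  One backward sweep per horizon.  The hazard defaults
  to central differences of −ln S_R with half-width 0.05 y; an
  augmented-ODE exact derivative (integrating ∂u/∂t alongside u) is also
  implemented and used to validate the differences (tests show < 1%
  relative disagreement, dominated by the O(δ²) difference error).

Validation: the α = β = 0 closed form (two-stage exponential race) is
matched to better than 10⁻⁶ over τ ∈ [0, 50] y; the identity
S = exp(−∫h) holds to < 10⁻⁴ relative on a quarter-year grid; the
homogeneous and general paths agree to 10⁻⁷ in S; and Monte-Carlo
no-plaque fractions from the simulator agree within 3 binomial standard
errors across parameter sets spanning the fit box with ν₂ from 10⁻⁷ to
10⁻³ per year.  Solved grids are cached by timeline content, which is what
makes stratified cohort fitting fast: workers sharing covariate categories
(and dose histories, when a dose response is active) share one solve.

## The simulator

The Monte-Carlo engine draws, per sub-annual step (365/year by default),
independent Poisson counts for influx, births, deaths, conversions and
plaque seedings with means rate × state × dt evaluated at the step start,
then applies them simultaneously.  This aggregate update is
distributionally equivalent to per-cell events in the dt → 0 limit at O(1)
cost per step.  M and F are floored at zero (flooring is counted; at the
default resolution it is rare), a plaque seeding decrements F by one so
conversions are exactly conserved, and rates are re-evaluated once per
simulated year, matching the solver's timeline.  Replicate i draws from a
stream seeded from (base_seed, i), so results do not depend on how
replicates are batched.

## Cohort likelihood and fitting

Worker i contributes lᵢ = S(aᵢ,out)/S(aᵢ,in)·h(aᵢ,out)^δᵢ; the left ratio
conditions on being stroke-free at entry (follow-up starts at first
employment).  Constant factors are dropped, so only deviance differences
are meaningful.  S is interpolated log-linearly between grid nodes
(piecewise-exponential survival), h linearly; a case at an age where the
model's hazard vanishes contributes −∞, which is reported as +∞ deviance
with diagnostics rather than silently dropped.  Deviance is additive and
invariant under record order; the stratified fast evaluation is tested to
agree with the naive per-record evaluation to 10⁻⁸.

Fitting is bounded multi-start local minimization (L-BFGS-B with a
derivative-free polish on line-search failures; 5 seeded start points by
default).  The optimizer's identity is irrelevant to the statistics —
deviance comparisons define the fit.  Infeasible points (β < 0, non-positive
dose factors) repel the search via infinite deviance.  95% confidence
intervals are profile-likelihood intervals: the bound is where the
re-optimized deviance rises by χ²₁(0.95) = 3.84 (the e^−1.92 rule), found
by bracketed root search; bounds clipped by the box are reported at the box
limit and are conservative.  Likelihood-ratio tests use the χ² upper tail
with the nesting degrees of freedom; on null synthetic cohorts the Δdev of
one spurious parameter is verified to follow χ²₁ (KS test over 200
replicates).

The risk-factor scan refits the model once per candidate rate with the
covariate's multipliers freed, reproducing the model-selection procedure
that asks which disease step a risk factor acts on.  Candidates acting
late (γ, ν₁, ν₂) are near-degenerate targets at realistic case counts —
the scan's deviance table makes that visible rather than hiding it.

## The empirical benchmark

The descriptive model is h = exp(b₀ + f_age(a) + f_year(y))·Π(factors)·
(1 + λd·1[a < μ]) with piecewise-linear f_age (knots 40 and 60 y; one
slope plus two slope changes — 3 parameters) and f_year (knots 1970 and
1990, linear already before the first knot).  Knot placement and the
linear-in-age (rather than log-age) form are reconstructions; the
parameter counts (3 age + 3 calendar) are the anchored facts.  Because the
log-hazard is linear in age within each annual segment, cumulative hazards
integrate in closed form (no quadrature error).  The radiation cutoff μ
makes the likelihood piecewise constant in μ, so μ is profiled on a 1-year
grid rather than passed to a smooth optimizer; when μ is profiled, the
Δdev of the radiation term cannot be referred to χ²₁.

The structural contrast that motivates the mechanistic model: a
multiplicative covariate gives an exactly age-constant hazard ratio, while
a covariate acting on ν₂ mechanistically yields a ratio that starts at the
multiplier just above t_lag and falls with age, because high-burden
carriers of the risk factor leave the risk set earlier (selection).  At
the default fitted parameter set this decline is strict over ages 11–90;
at strongly elevated ν₂ (10⁻⁵/y and above, used only to boost event counts
in oracle tests) the ratio passes through a minimum at high ages — a
saturation effect of the model, not a numerical artifact.

## The synthetic cohort generator

The generator emulates the structure of a mid-century occupational cohort:
male workers hired uniformly over 1948–1972, follow-up from first
employment to stroke, death, emigration or the administrative cutoff
(end of 2008), covariates fixed at entry, annual external gamma doses
during employment.  Stroke ages are drawn by inverse-CDF sampling from the
generating truth's analytic survival, left-truncated at entry (U uniform
on (0, S(a_in))); the stochastic simulator is retained as an independent
sampling path and the two distributions are KS-tested against each other.
Censoring is drawn independently of the latent cell state
(non-informative): Gompertz other-cause mortality (level 0.005/y at age
40, log-slope 0.085/y), exponential emigration (0.025/y) and the
administrative cutoff.  These levels were chosen so that a generated
cohort of 14,056 workers carries roughly 22 person-years per worker and an
8% case fraction — the scale of the cohort the analysis emulates.

Dose histories are lognormal per worker-year (annual σ = 0.8) with a
lognormal worker-level frailty (σ = 1.1) and an early-era excess decaying
at 8%/calendar-year from 1948; the overall scale is solved on the drawn
sample so the median cumulative dose is exactly the 0.28 Gy target, which
leaves the >2 Gy tail fraction at 5–10%, matching the emulated dose
distribution.  Entry ages (normal, mean 22, sd 5, truncated to 18–45) and
employment durations (lognormal, median 12 y) are generator assumptions —
no distributional facts about the real cohort stand behind them.

What passing recovery tests show — and what they do not.  The generator
draws from the same model family the fitter assumes, so recovery tests
validate the likelihood machinery, identifiability and interval coverage,
not the biological adequacy of the model for real cohorts.  Real data
carry pre-employment health selection (workers were medically screened at
hire, so early follow-up is healthier than the model assumes),
burden-correlated competing mortality at high ages, covariates measured
once rather than followed, and dosimetry error; none of these are
generated by default.  An optional entry-screening filter exists but is
off by default.

## Reproducibility and sizes

Every stochastic entry point takes an explicit seed; generated cohorts are
bit-reproducible from (design, seed), and CLI runs write a provenance
block (seed, version, config hash).  The validation suite uses 2000
simulator replicates for oracle comparisons, a 10,000-worker cohort for
the headline recovery experiment, 20 cohorts of 5,000 for γ-interval
coverage, and 200 cohorts of 800 for likelihood-ratio calibration — sizes
at which the binomial/χ² acceptance bands are informative while the whole
suite runs in a few minutes on one CPU.

## Known limitations

* Only first strokes are modelled; no recurrence, no plaque morphology or
  spatial structure, no explicit monocyte dynamics.
* The lag t_lag is a fixed constant; competing death during the lag is
  censoring, not a model state.
* Surrogate variables on the hazard, empirical spline knots and the
  linear-in-age spline basis are reconstructions (documented above).
* Hazard factors on the mechanistic model weight annual log-survival
  increments with the factor at the interval start; for factors varying
  within a year this is first-order accurate.
* The fit box for γ excludes zero by construction; cohorts generated with
  γ at or below 0.1/y will be boundary-censored.
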