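# Methods

## Model overview

`ironburden` estimates the annual burden of dietary iron deficiency (ID) and
iron-deficiency anemia (IDA) for a national population divided into 17
strata (gender × age class × menstrual/menopausal status). The causal chain
is:

1. **Deficiency.** A person is iron-deficient when absorbed dietary iron
   falls below their physiological requirement. Absorbed intake in a stratum
   is lognormal, `X ~ LogN(μ, σ)` (mg/day, absorbed scale); the requirement
   is normal, `R ~ N(m, s)` (EFSA average requirement and spread). ID
   prevalence is `P(X < R)`.
2. **Anemia.** `Prev.IDA = Prev.ID × Prop.IDA`, with `Prop.IDA` a
   per-stratum constant in [0, 1] derived from observed ID/IDA/anemia
   ratios. Strata with `Prop.IDA = 0` carry deficiency but no anemia burden.
3. **Severity.** The anemic fraction of the stratum's normal hemoglobin
   distribution `Hb ~ N(h, σ_h)` is partitioned at the WHO thresholds into
   mild/moderate/severe bands, in closed form:
   `A = Φ(z(t_mild))`, `alloc_severe = Φ(z(t_sev))/A`,
   `alloc_moderate = (Φ(z(t_mod)) − Φ(z(t_sev)))/A`,
   `alloc_mild = (Φ(z(t_mild)) − Φ(z(t_mod)))/A`, `z(x) = (x − h)/σ_h`.
   The same partition is applied to the ID-attributable subset.
4. **Cases and DALYs.** `NB_s = Pop × Prev.IDA × alloc_s` and
   `DALY = Σ_s NB_s × w_s` with disability weights
   `w ~ N(0.005, 0.002) / N(0.058, 0.012) / N(0.164, 0.030)` for
   mild/moderate/severe, truncated at 0. No mortality term is modeled
   (DALY = YLD), and the disability duration is one year, so all outputs are
   annual. No age weighting or discounting.

Rates are reported per 100,000 of a whole-population reference denominator
(default 61,800,000), deliberately larger than the 53.9 M sum of stratum
populations: the strata cover ages 3–74 and exclude pregnant women, while
published rates are per 100,000 of the entire country.

## Separation of uncertainty and variability (second-order Monte Carlo)

Inputs are classified once: intake parameters carry **uncertainty**
(sampling error of a fit), requirement and hemoglobin distributions carry
**variability** only (biological spread, assumed known), `Prop.IDA`,
populations and thresholds are deterministic, and disability weights are
classified as **uncertainty** shared across strata (a weight is a property
of the health state, not of a subgroup; sharing the draws widens aggregate
intervals accordingly).

The engine nests two loops:

* **Outer (uncertainty), `n_unc = 1000`:** draw one `(μ, σ)` intake pair —
  from bootstrap replicates when fitted from records, or from independent
  normals `N(point, (CI_hi − CI_lo)/3.92)` when only a published point
  + 95% CI exists — plus one disability-weight triplet per iteration.
* **Inner (variability), `n_var = 10,000`:** draw requirement values
  `r_j ~ N(m, s)` and average the *lognormal CDF* evaluated at each draw.
  Integrating the intake dimension in closed form (Rao-Blackwellization)
  leaves the same estimand as sampling intake jointly — the unit tests
  verify this against brute-force joint sampling — with strictly lower
  variance. Requirement draws at or below zero contribute CDF = 0 and are
  kept, not redrawn: truncating them would bias prevalence upward exactly
  in the strata (menstruating women, `N(1.41, 0.76)`) where the needs
  distribution has visible negative mass.

Every scalar result is carried as a vector over the 1000 outer iterations
(`UncertainEstimate`) and summarized as mean and percentile 2.5/97.5.
Aggregation across strata sums these vectors iteration-wise before
summarizing, so national intervals inherit the shared weight draws.

### Numerical choices

* **Antithetic sampling in the uncertainty dimension.** CI-normal parameter
  draws are generated in `(z, −z)` pairs and weight draws in `(u, 1 − u)`
  pairs through the truncated-normal inverse CDF. Marginal distributions —
  hence the reported percentile intervals — are unchanged; the Monte Carlo
  error of run *means* collapses. This is what makes the documented
  stability contract (three seeds, max relative per-stratum DALY deviation
  < 1% at default iteration counts; measured ≈ 0.6%) attainable: with naive
  sampling the mild weight's 40% coefficient of variation alone leaves
  ≈ 1.3% standard error on a 1000-iteration mean.
* **RNG streams.** One root seed; each stratum, the weight sampler, the
  synthetic generator and the scenario fitting/simulation stages own
  deterministic child streams (`SeedSequence(seed, spawn_key=...)`), so any
  stratum is reproducible in isolation and scenario doses share common
  random numbers (below).
* **Redraws.** CI-normal samplers can produce `σ ≤ 0`; the engine redraws
  those and warns if redraws exceed 1% of iterations.
* **Degenerate limits.** `RequirementModel` accepts `sd = 0`, `DisabilityWeight`
  accepts `sd = 0`, and a point parameter sampler exists, so the whole
  pipeline collapses to a deterministic composition of normal/lognormal
  CDFs; the test suite asserts machine-precision agreement with an
  independently coded version of that composition.
* **Precision.** Internal accumulation is full precision; rounding happens
  only at presentation.

## Parameter registry

The packaged configuration (`data/france_2007.json`) transcribes the
published national inputs for metropolitan France, 2007: population counts,
absorbed-intake lognormal fits with 95% CIs (from a national dietary survey
absorbed at flat EFSA coefficients — 10% for ages 3–11, 16% for adolescents
and adult males, 18% for adult females), EFSA requirement distributions,
ID→IDA proportions, hemoglobin distributions, WHO severity thresholds and
GBD disability weights. The stratum grid is irregular by design: males carry
a merged 12–17 class; females split adolescence into 12–14 (assumed
non-menstruating) and 15–17 (menstruating, with adult-female iron needs);
women 15–24 are always premenopausal, 65–74 always postmenopausal.

The severity-threshold row of the source table is typographically damaged;
the shipped thresholds (3–6: 10.9/9.9/7.0; 7–11: 11.4/10.9/8.0; females
12+: 11.9/10.9/8.0; males 12–17: 11.9/10.9/9.0; males 18+: 12.9/10.9/8.0
g/dL for mild/moderate/severe cut-offs) follow the WHO bands used by the
GBD anemia work and were verified to reproduce the published per-stratum
DALY values through the closed-form chain. The severe-band mapping is
numerically negligible for every shipped hemoglobin distribution (severe
mass < 10⁻³ of the anemic fraction); anyone extending the registry should
re-derive it from primary WHO sources.

Two cells of the source's own results tables are mutually inconsistent with
its printed inputs (one male intake cell is a verbatim duplicate of the
neighboring female cell; a second male stratum's printed prevalence cannot
be produced from its printed intake and needs under any reading). The
registry transcribes the printed inputs verbatim; the test suite asserts
every internally consistent cell and excludes those two (plus one
interval typo), with the full analysis recorded in the project's review
notes outside the package.

## Survey ingestion

When individual records are available (real or synthetic), ingestion:

1. resolves unknown pregnancy/menopause answers with a fixed decision table
   (menopause unknown and not pregnant → menopausal iff age > 50; pregnancy
   unknown and not menopausal → assumed pregnant; under 18 → not pregnant;
   otherwise unresolved and ≤ 50 → premenopausal), excludes pregnant women,
   and is idempotent;
2. maps each person to the stratum grid (women 25–64 split by the resolved
   status, 15–24 forced premenopausal, 65–74 forced postmenopausal);
3. multiplies intake by the person's absorption coefficient; and
4. fits `LogN(μ, σ)` per stratum by maximum likelihood (closed form:
   `μ = mean(log x)`, `σ = population-sd(log x)`), with a nonparametric
   bootstrap (default B = 1000 resamples, fitting floor n = 30 — package
   defaults, chosen as conventional values) supplying the uncertainty
   replicates consumed by the outer Monte Carlo loop. One unit test
   cross-checks the MLE against R's `fitdistrplus::fitdist`.

## Consumption scenarios

A scenario replaces each person's current red-meat iron with a fixed dose
of cooked ground beef (grid 0/25/50/75/100 g/day): absorbed intake becomes
`(iron − red_meat_iron) × coefficient + dose × 2.6/100 × 0.25` — the
subtracted component absorbs at the flat coefficient the baseline
distributions were built with, while added beef heme iron absorbs at 25%.
Dose 0 is the no-red-meat counterfactual, which is why its prevalence sits
*above* the observed baseline. Each dose refits the stratum lognormals
(bootstrap), reruns the engine and the burden chain, holding `Prop.IDA`
fixed across doses (the anemia-to-deficiency ratio is assumed
dose-invariant; the output audits this identity). Scenarios require
individual records — a per-person subtraction changes the distribution's
shape, not just its location, so no analytic shift of the fitted parameters
would be faithful. Substitution effects, acceptability, and offsetting
health risks of red meat are out of scope.

## Synthetic survey generator

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable without the (unpublished) survey microdata:

* raw-scale total iron per stratum: `LogN(μ − log(coef), σ)`, i.e. the
  published absorbed-scale parameters un-shifted by the absorption
  coefficient, making the generated records exactly consistent with the
  registry after ingestion re-applies the coefficients;
* red meat: zero-inflated gamma — 20% non-consumers, consumer mean chosen
  so the overall mean is 18.2 g/day (the reported national mean), shape 1.2
  (right-skewed; dispersion and zero inflation are fixture knobs, not
  claims about the survey); red-meat iron = grams × 2.6 mg/100 g, capped at
  total iron (an error is raised if more than 10% of draws would need
  capping);
* demographics: ages uniform within the class, unknown menopause/pregnancy
  answers injected at 10%/5% among adult women, 3% pregnancy among women
  18–50.

It does **not** emulate survey sampling weights, multi-day diary structure,
food-item granularity, or any intake–red-meat correlation beyond the cap.
Passing tests therefore demonstrate the pipeline's correctness and internal
consistency on data with the assumed structure, not robustness to the messiness
of real dietary surveys.

## Problem sizes used by the tests

The shipped test suite runs the national pipeline at full size
(1000 × 10,000; a few seconds per run) including the three-seed stability
check, and scales the record-based pathways to keep the whole suite under a
minute: synthetic fixture of 2000 records/stratum, bootstrap B = 150–300,
scenario grids at 150–200 outer × 800–1500 inner iterations with common
random numbers across doses (dose-monotonicity asserted with 2% Monte Carlo
slack), and bootstrap-coverage checks at 50 repetitions of n = 2000
(coverage asserted in [88%, 100%]).

## Known limitations

* The ID definition is intake-below-average-requirement; it is not the
  ferritin-depletion definition used by some surveys, so prevalence levels
  are not directly comparable across definitions.
* `Prop.IDA`, thresholds and populations are deterministic inputs; their
  uncertainty is not propagated. Hemoglobin and requirement parameters are
  variability-only.
* Children under 3, adults over 74 and pregnant women are outside the
  stratum grid; the per-100k denominator nevertheless spans the whole
  population, matching the source convention.
* The one-year disability duration makes DALY equal to annual YLD; no YLL,
  age weighting or discounting.
* Scenario outputs on synthetic records are qualitative: the real
  per-person red-meat iron distribution is unpublished, so dose-response
  *properties* (monotonicity, non-elimination at 100 g/day) are asserted
  rather than published curve values.
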