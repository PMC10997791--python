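# Methods

## Model and assumptions

For phenotype *j* tested separately in two ancestry strata *g* ∈ {1, 2},
the inputs are regression coefficients β̂ⱼᵍ with standard errors seⱼᵍ
(log odds ratios per minor-allele copy for binary traits; changes in log
lab value for continuous traits).  The working assumption is the usual
large-sample one: β̂ⱼᵍ ≈ N(βⱼᵍ, seⱼᵍ²), independently across strata (the
strata are disjoint subject sets) and approximately across phenotypes.

Two hypotheses per phenotype: the *mean* hypothesis (pooled effect zero)
and the *heterogeneity* hypothesis H₀ⱼ: βⱼ¹ = βⱼ².  The procedure targets
FDR control over the heterogeneity hypotheses only; the mean statistics
serve as an auxiliary covariate.

### Step I

With wᵍ = se⁻²: pooled effect β̂ⱼ = (w¹β̂ⱼ¹ + w²β̂ⱼ²)/(w¹+w²), its standard
error (w¹+w²)^−½, standardized statistic zⱼ, and two-sided normal p-value;
heterogeneity statistic Qⱼ = (β̂ⱼ¹−β̂ⱼ²)²/(se₁²+se₂²) with an upper-tail
χ²₁ p-value.  Under independent strata, cov(β̂ⱼ, β̂ⱼ¹−β̂ⱼ²) =
(w¹se₁² − w²se₂²)/(w¹+w²) = 0: the pooled mean and the difference are
exactly uncorrelated, hence asymptotically independent — the property that
lets any function of zⱼ re-weight the heterogeneity p-values without
distorting their null distribution.  p-values are floored at 1e-300 so
later division by weights cannot underflow to zero.

### Step II

The weighting function is estimated by a logit-link regression of the
exceedance indicator yⱼ = 1{p_het,ⱼ ≤ τ} (τ = 0.01 by default) on a basis
of uⱼ = min(|zⱼ|, 5):

* **Truncation at |z| = 5.**  The prior being encoded is that
  heterogeneous effects occur at phenotypes whose mean effect is *present*;
  beyond |z| = 5 (p ≈ 6·10⁻⁷) presence is no longer in doubt, so further
  magnitude should not raise the weight.  Without truncation, phenotypes
  whose pooled z is deflated by the imbalance (the pooled estimate leans
  toward the majority stratum, which for a heterogeneous phenotype can sit
  on the smaller of its two group effects) would receive systematically
  smaller weights than equally-active homogeneous phenotypes.
* **Basis.**  [1, u, u²] ("quadratic", default) or [1, u] ("linear").  The
  sign of z is discarded: the prior concerns presence, not direction.
* **Threshold τ = 0.01.**  τ sets the null floor of the training
  response: null heterogeneity p-values land below it at rate τ regardless
  of u, while genuinely heterogeneous phenotypes land below it with their
  (much larger) power at that cut.  A small τ therefore maximizes the
  contrast between the active cluster and the null floor; 0.01 keeps the
  response informative at phenome scale (m ~ hundreds of null exceedances
  is unnecessary — a handful suffice to anchor the floor) without making
  it degenerate.  Configurable; the procedure's FDR control held across
  the tested design grid at every τ examined.
* **From propensity to weights.**  Writing π̂(u) for the fitted exceedance
  propensity, null p-values exceed the threshold at a rate that does not
  depend on u, so the excess of π̂ over its own fitted minimum
  (divided by 1−τ) estimates the local fraction of truly heterogeneous
  phenotypes.  Excess smaller than its delta-method standard error
  is treated as noise and zeroed — this keeps phenotypes with no real
  enrichment at the weight floor instead of letting fit noise leak budget
  to them.  Raw weights are scaled to mean 1, clamped to
  [w_min, w_max] = [0.05, 20], and re-normalized iteratively
  (tolerance 1e-6).
* **Leave-one-out correction.**  Each phenotype's own exceedance
  indicator enters the regression, so its fitted propensity — hence its
  weight — is mildly correlated with its own p-value, which measurably
  inflates the realized FDR when the active set is small.  The model
  therefore stores, for every training phenotype, a one-step leave-one-out
  propensity (working-residual/leverage form of the IRLS fit): when
  weights are computed for the phenotypes the model was fitted on, no
  hypothesis is weighted by a function of its own p-value.  This costs a
  little power (a truly heterogeneous phenotype loses its own vote for a
  high weight) and is the price of finite-sample honesty without sample
  splitting.
* **Fallbacks.**  Unit weights (reducing Steps II–III exactly to the
  unweighted base procedure) whenever: fewer than 20 phenotypes; the
  training response is all-0/all-1; the fit fails; no excess survives the
  noise threshold (nothing to learn — the soft-thresholding doubles as an
  informativeness gate); or the fitted propensity *decreases* from u = 0
  to the largest observed u (contradicting the prior).  Every fallback
  carries a warning and a recorded reason.

Mean-1 weights are the standard validity condition for weighted FDR
procedures: at any threshold t, the expected number of weighted null
rejections is at most t·Σ_null wⱼ ≤ t·m.

### Step III

qⱼ = min(p_het,ⱼ/wⱼ, 1) is passed to a base FDR procedure at α = 0.1
(the level used throughout).  The base is pluggable: Storey's adaptive BH
(default; π₀ estimated at λ = 0.5, capped at 1, floored at 1/m) or plain
BHq.  Ties are broken by a stable sort on (q, phenotype_id) so output is
byte-reproducible regardless of input order.

## PheWAS engine

Per stratum: a subject is a case for a PheCode if it occurs ≥ 2 times
(single mentions count as control); codes at prevalence ≤ 0.5% are
excluded, as are integer-level codes with a retained decimal descendant
(hierarchy derived purely from the code strings, e.g. 250 → 250.1/250.2);
logistic regression of case status on dosage + age + sex + follow-up years
+ log total PheCode count; labs are reduced to the per-subject median,
log-transformed, and fitted by OLS with the same covariates (≥ 30 measured
subjects required).  A constant covariate (sex, in a heavily male cohort)
is dropped with a warning; non-convergent or separated fits, all-case /
all-control codes and constant-dosage strata are skipped with logged
reasons rather than imputed.  Phenotypes surviving in both strata are
paired for Steps I–III; the rest are reported separately.  Filtering and
prevalence are per stratum, and exactly 0.5% prevalence is excluded
("0.5% or less").

Open choices resolved here: follow-up is measured in years; utilization
counts total (not distinct) code occurrences and enters as a natural log.

## Simulation design

### Summary-statistics benchmark (the workhorse)

Per replicate: m = 1000 phenotypes; 50 *active* (non-zero pooled effect
±μ, sign random), of which 10 *heterogeneous* (group effects μⱼ ± δ/2, the
split sign random — heterogeneous phenotypes therefore retain non-zero
means, matching the prior the weighting exploits); the rest null.
Observed β̂ᵍ ~ N(truth, σ²/nᵍ) with n_major = 8000, minority ratio 0.25,
σ = 1.  Defaults μ = 0.08, δ = 0.075.

μ and δ are not identified by any external constraint, so they were fixed
by a pre-registered calibration (`scripts/calibrate.py`): δ is the grid
point {0.07 … 0.08, step 0.0025} at which the *unweighted BH baseline's*
power is nearest 0.3 — mid-band of the 0.1–0.6 window in which procedure
differences are observable — and μ = 0.08 puts active phenotypes at pooled
|z| ≈ 8, i.e. unambiguously active, as real phenome-wide mean-effect hits
are.  At these defaults (400 replicates, α = 0.1) the package's own
benchmark measures hetFDR at empirical FDR ≈ 0.08 with average power
≈ 0.68 versus ≈ 0.30 for BHq and Storey.

### Individual-level cohort generator

For end-to-end tests of the PheWAS engine: two strata with
Hardy–Weinberg dosages at MAF 0.14 (AFR) / 0.40 (EUR); age
N(62.1, 13.9²) truncated to [18, 100]; follow-up N(12.5, 5.7²) truncated
positive; 91.3% male; log-normal utilization.  Binary phenotypes are
Bernoulli under a logistic model (control-scale prevalence mostly 3–15%,
plus deliberately rare codes below the 0.5% floor and a 250/250.1/250.2
parent-child triple to exercise the filters; 3% of controls receive a
single code occurrence so the ≥2 rule is load-bearing); labs are
log-normal with 1–3 repeated measurements per subject.  The default plan
spans 280 phenotypes (220 codes, 60 labs) with 32 active / 12
heterogeneous — the same order of screen width as a real single-variant
PheWAS after filtering.

What the generator does *not* emulate: linkage disequilibrium and
multi-SNP genotypes, relatedness and admixture, code-correlation across
phenotypes (draws are independent given covariates), informative missing
data, and secular EHR trends.  Passing tests therefore demonstrate the
statistical machinery under the stated sampling model, not robustness to
those real-data features.

## Numerical choices and degenerate inputs

* p-value floor 1e-300; standard-error floor 1e-8 in the noiseless
  simulation limit.
* Weight clamp [0.05, 20] with iterative clamp/re-normalize (≤ 100
  iterations, tolerance 1e-6); the clamp prevents any single phenotype
  from absorbing the whole FDR budget.
* Logistic fits: IRLS (statsmodels GLM), 200 iterations for the weight
  model, Newton with 100 iterations for the PheWAS engine; any exception,
  non-finite estimate, or se > 1000 (separation symptom) triggers the
  documented fallback/skip path.
* Empty inputs return empty outputs; duplicate phenotype ids, mismatched
  lengths, out-of-range probabilities, and non-positive standard errors
  raise with the offending identifier.
* FDP of an empty rejection set is 0 (max(R, 1) convention); power is
  undefined (reported missing) when the truth contains no heterogeneous
  phenotype.

## Known limitations

* Weights are estimated on the same p-values they are applied to; the
  soft-thresholding step empirically removes the resulting FDR inflation
  at phenome scale (m ≥ a few hundred), but very small screens (m ≈ 100)
  retain some, and the guarantee is asymptotic, not finite-sample.
* The two-stratum construction is essential; more than two groups would
  need a different heterogeneity statistic and is out of scope.
* The heterogeneity test assumes well-estimated standard errors; rare
  phenotypes near the prevalence floor in the minority stratum can have
  unstable logistic fits, which the engine skips rather than repairs.
* Fixed-effect pooling only; no random-effects meta-analysis or
  between-stratum covariance.
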