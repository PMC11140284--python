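# Methods

This note documents the statistical models implemented in `vistraj`, the
assumptions behind the synthetic cohort generator, the numerical choices,
and the known limitations. It is the package's own account of its methods;
no empirical number stated here is asserted anywhere except where the test
suite or the acceptance script computes it.

## The scientific setting

The package analyses repeated measurements of a coarse visual-function
score (1 = blind … 4 = able to see and distinguish a Landolt-C break)
taken at four survey waves in an ageing cohort. The questions it answers,
in order: does vision follow a common linear course; are there latent
subgroups with distinct courses; which baseline characteristics predict
subgroup membership; and do the subgroups differ in distal health outcomes
(cognition, ADL/IADL dependence, depression, anxiety, fall risk) measured
at the final wave.

## Latent linear growth-curve model (LGCM)

For subject *i* with wave scores `y_i` (length *p* = 4) and wave times
`t = (0, 1, 2, 3)`:

    y_i = Λ η_i + ε_i,    η_i ~ N(α, Ψ),    ε_i ~ N(0, Θ)

with loadings `Λ = [1 | t]`, growth-factor means `α = (α0, α1)` (intercept
= level at the first analysed wave, slope = change per wave), factor
covariance `Ψ` (2×2), and diagonal residual covariance `Θ` (wave-specific
by default, 4 free variances; an equal-variance option exists). Implied
moments are `μ = Λα`, `Σ = ΛΨΛ' + Θ`; the model spends 9 of the 14
observed moments, leaving 5 df.

Estimation maximises the Gaussian likelihood with `scipy` L-BFGS-B over
`(α, chol(Ψ), log θ)`, started from per-subject OLS moment estimates plus
one fallback start; convergence at log-likelihood change < 1e-8. With
`allow_partial`, subjects contribute their observed waves
(full-information ML over missingness patterns), subject to a minimum of
3 observed waves — the design of the sensitivity analysis for cohorts
with attrition.

### Fit indices

The ML discrepancy is

    F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (ȳ−μ)'Σ⁻¹(ȳ−μ)

with test statistic `T = (n−1)F` (Mplus uses a factor differing by
n/(n−1); negligible at n ≈ 2000 and documented rather than emulated).
CFI, TLI and RMSEA use the standard formulas with an independence
baseline (free means and variances, zero covariances); SRMR is computed
on standardised covariance residuals only (lower triangle including the
diagonal), the most common convention — mean residuals are excluded.
CFI/TLI are clamped to [0, 1]. With partial data the saturated model is
fitted by an EM for the unstructured multivariate-normal mean/covariance
and `T = 2(LL_sat − LL_model)·(n−1)/n`.

## Growth mixture model (GMM)

The K-class mixture shares `Ψ` and `Θ` across classes; classes differ only
in `α_k` — the conventional default growth-mixture specification, and the
only one identifiable from the published report, which gives class means
but no class-specific variances. The observed-data log-likelihood is

    LL = Σ_i ln Σ_k π_k N(y_i; Λα_k, ΛΨΛ' + Θ)

over each subject's observed waves.

**EM.** Class labels and growth factors are both treated as missing data,
giving closed-form updates: `π_k` as posterior means; `α_k` as
posterior-weighted means of the conditional factor expectations; `Ψ` and
`Θ` from the expected complete-data sufficient statistics. The M-step
uses the parameter-expansion device for random-effects models (PX-EM):
the expanded model `y = ΛAη + ε` is also maximised over an auxiliary 2×2
transform `A` (a small generalised-least-squares solve, one Sylvester
term per missingness pattern), then reduced back via `α_k ← Aα_k`,
`Ψ ← AΨA'`. This leaves the fitted model unchanged but removes the
notoriously slow Ψ/Θ partitioning direction of the plain EM — orders of
magnitude fewer iterations on weakly separated data — while keeping the
observed-data log-likelihood monotone, which is checked at every
iteration and recorded on the fit. Convergence: absolute log-likelihood
change < 1e-6, at most 500 iterations per start (both configurable; near
a variance boundary EM may still use its full budget — the best solution
is then returned with `converged=False`). Complete-data cohorts take a
fully vectorised iteration path that is algebraically identical to the
general missingness-pattern path.

**Multi-start.** Default 50 starts: the first from k-means on per-subject
OLS (intercept, slope) estimates, the rest from random-centroid hard
assignments of those estimates, softened to 0.9/0.1 responsibilities. All
randomness is seed-controlled. Degenerate starts (empty class, singular
covariance) are recorded and skipped; an error is raised only if every
start fails.

**Safeguards.** Variance floors θ_w ≥ 1e-4 and eigenvalues of Ψ ≥ 1e-6
prevent degenerate likelihood spikes; activations are counted on the fit.
Classes are stored in canonical order (descending intercept mean), which
resolves label switching; for K = 2 the canonical classes carry the
field's names, "high-baseline decline" and "low-baseline improvement".

### Enumeration statistics

* AIC = −2LL + 2p, BIC = −2LL + p·ln n, aBIC = −2LL + p·ln((n+2)/24),
  with p = 2K + (K−1) + 3 + 4 free parameters (12 at K = 2).
* Relative entropy `E = 1 − Σ_ik(−p_ik ln p_ik)/(n ln K)`, in [0, 1],
  undefined (NA) at K = 1.
* **BLRT**: parametric bootstrap of `2(LL_K − LL_{K−1})`; B cohorts are
  simulated from the fitted (K−1)-class model, both models are refitted
  (with a reduced start budget), and `p = (1 + #{LRT_b ≥ LRT_obs})/(B+1)`.
  A replicate that fails after the retry cap is counted conservatively as
  exceeding the observed statistic. The smallest attainable p is
  1/(B+1), so B ≥ 20 is needed for significance at 0.05; the default is
  B = 100.
* **LMR**: implemented as a documented approximation — a Bartlett-style
  small-sample correction `2ΔLL / (1 + 1/(d ln n))` referred to χ²_d with
  d the parameter difference. The exact LMR reference distribution (a
  weighted chi-square sum) is not reproduced; the result is flagged
  approximate, and the BLRT is the authoritative test.

**Selection rule.** The selected K is the largest K such that at *every*
step k ≤ K both LMR and BLRT reject at α = 0.05 **and** every modal class
holds at least 5% of the sample. The walk stops at the first failing
step; the per-K table and a trace of which rule fired are always
reported. Requiring both tests is what reproduces the published
enumeration (the K = 3 step there fails on the LMR despite a significant
BLRT).

## Screening and regression models

* Categorical predictors: uncorrected Pearson χ² (`scipy`), which
  reproduces published class-by-level tables exactly; a zero margin is an
  error naming the degenerate category.
* Continuous predictors: Mann-Whitney rank-sum with midranks and a
  tie-corrected normal approximation for Z (scipy does not expose the Z
  statistic, so it is assembled from `rankdata`); medians (IQR) reported.
  A t-test option exists but is off by default, matching the
  median-based reporting convention.
* Class membership model: ML logistic regression (`statsmodels`), outcome
  1 = high-baseline decline, with Wald SEs; quasi-separation and singular
  designs raise errors naming the offending terms. Categorical predictors
  are dummy-coded against fixed reference levels (male, rural, living
  with family, non-professional, no formal qualifications, poor economic
  status, not married, never-smoker, rare drinking, rare exercise, low
  fruit frequency, disease absent).
* Distal outcomes: OLS for continuous scales, logistic for fall risk.
  "Model 1" is the bare class contrast (its coefficient equals the raw
  class-mean difference exactly); "model 2" adds sex, birthplace,
  residence, occupation, education, economic status, marital status.
  All 95% CIs use 1.96·SE on the link scale; odds-ratio CIs exponentiate
  the bounds. No multiple-testing correction is applied (matching the
  emulated analysis). Class membership enters by modal assignment;
  bias-adjusted three-step methods are out of scope and this is a known
  limitation (modal assignment attenuates contrasts when entropy is
  moderate).
* Dose-response: restricted cubic spline in the truncated-power form,
  linear beyond the boundary knots, K−2 nonlinear terms scaled by
  1/(t_K − t_1)²; default 4 knots at the 0.05/0.35/0.65/0.95 quantiles,
  curve centred at a reference exposure (BMI 21.0 by default, so the
  curve is exactly 0 there). Nonlinearity is a Wald test that all
  nonlinear coefficients vanish.
* Multiple imputation: chained equations — linear regression plus normal
  noise for continuous variables, (multinomial) logistic draws for
  binary/categorical — over 5 sweeps and m completed datasets, pooled by
  Rubin's rules `T = W̄ + (1 + 1/m)B`. Parameter uncertainty is not
  redrawn per imputation (stochastic regression rather than fully
  Bayesian imputation); with MCAR missingness at the rates exercised here
  the pooled estimates are unbiased, which is what the tests check. With
  no missing data the call reduces to the direct fit (B = 0).

## Synthetic cohort generator

The generator is the package's study design: it draws classes from
Categorical(π), growth factors from N(α_k, Ψ), scores from the linear
growth model, baseline predictors from class-conditional distributions,
and outcomes from class-shifted linear/logistic models, with optional
MCAR masking of individual vision observations and optional clamping to
the 1–4 instrument range.

The packaged `paper_like` configuration encodes the published two-class
solution: π = (0.819, 0.181), α₁ = (3.992, −0.174), α₂ = (2.641, 0.296).
Its predictor distributions are the published class-wise percentages
(e.g. cataract 4.9% vs 16.5%), continuous predictors are normals matched
to the published medians with IQR-based spreads (sd = IQR/1.349; skewness
is not modelled because only location contrasts matter downstream), and
outcome shifts are the published unadjusted class effects (e.g. cognition
+3.186). Outcome baselines and noise scales are package choices on the
scales' plausible ranges (cognition 24 ± 6, ADL 6.8 ± 2, IADL 11.5 ± 4.8,
depression 36 ± 5, anxiety 2.6 ± 2.4, fall ≈ 17% prevalence).

**Variance components.** The published report gives no within-class
variance components, so ψ00 = 0.30, ψ11 = 0.01, ψ01 = 0, θ_w = 0.20 are
package defaults, overridable in the config. Under these defaults the
two classes overlap appreciably: the relative entropy of the generated
mixture is about 0.73, well below the published 0.998, and modal class
shares run 1–3 points above the generating 81.9% because overlap
asymmetrically absorbs minority-class subjects. Parameter recovery (π̂,
α̂_k) is unaffected — the model is correctly specified — but tests on
modal shares use tolerances of a few percentage points rather than
binomial ones. Matching the published entropy would require much smaller
residual variances than the 1–4 ordinal instrument plausibly allows.

**Default generation is continuous with censoring off** for recovery
tests: clamping to [1, 4] truncates the normal tails and would bias
recovery of the generating parameters. The censored mode exists to mimic
the ordinal instrument. Attrition is MCAR only; informative dropout is
out of scope.

What passing tests on these cohorts do **not** show: robustness to the
ordinal 1–4 measurement (the real instrument has four levels, not a
continuum), to informative dropout, to survey weights or the cohort's
province structure, or to class-specific variance structures.

## Problem sizes and numerical choices

* Recovery tests and the acceptance script run at the published cohort
  size, n = 2235, with 50 EM starts; the two-class fit takes seconds.
* The BLRT uses B = 20 in tests (smallest p = 1/21 < 0.05) and B = 50–100
  in the analysis scripts. By default its bootstrap refits are
  warm-started from the generating/observed solutions, the usual trick
  for keeping the bootstrap affordable. Its null calibration is checked
  at n = 100, B = 19, 200 replicates with warm starts disabled and a
  capped EM budget applied identically to observed and bootstrap fits:
  the observed statistic is then exchangeable with the bootstrap ones,
  which is what makes the p-value uniform.
* Enumeration in the acceptance test runs to K_max = 3 (the step-2
  acceptance and step-3 veto are both exercised); the analysis script
  runs the full 1–4.
* Ties in modal assignment break toward the lower (higher-intercept)
  class index. Posterior rows sum to 1 within 1e-10.
* All generation and fitting is bit-reproducible given a seed; pipeline
  reruns with the same seed produce byte-identical reports.

## Known limitations

* LMR is an approximation (see above); decisions rest on the BLRT.
* Modal (most-likely-class) assignment is used downstream, as in the
  emulated analysis; with entropy ≈ 0.7 this attenuates class contrasts
  relative to bias-adjusted three-step estimators.
* The generator cannot reproduce published multivariable odds ratios or
  adjusted outcome models: those depend on the joint covariate
  distribution of the restricted microdata, which the class-conditional
  marginals do not determine. Univariate quantities (χ² tables, class
  means, unadjusted contrasts) are reproduced; multivariable results are
  validated by parameter recovery against the generator's own truth
  instead.
* Vision is treated as continuous Gaussian within class; the real
  instrument is a 4-level ordinal scale. Whether the published analysis
  treated it as censored/ordinal is not stated there; the continuous
  treatment is the package's documented assumption.
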