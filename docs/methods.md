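# Methods

## The scientific question and the model

Smokers develop systemic manifestations — reduced bone density and
muscle mass, arterial stiffening, insulin resistance, reduced kidney
function, shorter leukocyte telomeres, systemic inflammation — and it is
debated whether these are direct consequences of smoking or are mediated
by the lung damage of COPD. The package implements a structural equation
modeling (SEM) analysis of that question on a cross-sectional cohort of
smokers with COPD, smokers without COPD and non-smokers: smoking
exposure (pack-years) may affect each systemic outcome directly and/or
through two lung-function mediators, FEV1 (airflow limitation) and KCO
(alveolar diffusion). Two latent factors summarize correlated outcome
blocks: a *musculoskeletal factor* measured by ASMMI, hip BMD, lumbar
BMD, pinch and grip strength, and a *cytokines factor* measured by IL-6,
IL-8, TNFα and MCP-1. All structural equations are adjusted on age and
gender.

Three variants are provided: Model 1 (whole sample, FEV1 and KCO as
separate mediators), Model 2 (identical specification fitted on the
smoker subset, pack-years > 0, to remove the mass of structural zeros in
non-smokers), and Model 3 (FEV1 and KCO replaced by a single pulmonary
latent factor).

## Estimation

Models are declared as variables / loadings / directed paths /
covariances and translated to RAM form: directed coefficients in an
asymmetric matrix `A`, variances and covariances in a symmetric `S`,
means in `M`; with `B = (I − A)⁻¹` the implied observed moments are
`μ = F B M`, `Σ = F B S Bᵀ Fᵀ`.

Estimation is full-information maximum likelihood (FIML): each subject
contributes the multivariate-normal log-density of its observed
subvector, so partially observed rows are used as-is, without deletion
or imputation. Rows are grouped by missingness pattern once per fit and
each pattern is summarized by its count, mean and scatter; the gradient
of the log-likelihood is computed analytically by accumulating
per-pattern derivatives with respect to `(μ, Σ)` and chaining them
through the RAM identity. Optimization is quasi-Newton (L-BFGS-B) in
preconditioned coordinates — each parameter divided by its natural scale
(products of per-variable sample SDs) — which keeps the problem well
conditioned when raw-percentage variables (variance ≈ 900) sit next to
log-scale biomarkers (variance ≈ 0.02). Convergence requires the
optimizer's relative-likelihood criterion (`ftol` 1e−13) plus a
preconditioned gradient max-norm below 1e−4 per observation
(the likelihood and its gradient grow linearly with n, so an absolute
gradient threshold would be meaningless across sample sizes); up to 5
jittered restarts are attempted otherwise, and non-convergence is
reported through a flag rather than raised.

Identification follows the common ML-software default: the first
declared loading of each latent is fixed to 1 and the latent (residual)
variance left free; latent means are fixed to 0; a means structure is
always estimated. A unit-latent-variance alternative is provided and
tested to give the same standardized solution, which is how results are
reported: each coefficient `a → b` is rescaled by the model-implied
`sd(a)/sd(b)` (latents included). Exogenous observed variables that feed
the structural part receive free variances, means and pairwise
covariances. Negative variance estimates (Heywood cases) are not bounded
away — hard bounds distort standard errors — but are flagged in the
fit's warning list, as are standardized coefficients outside [−1, 1].

Standard errors come from the inverse of the observed information,
obtained by central differencing of the analytic gradient; z-ratios and
two-sided normal p-values follow. Standardized-scale standard errors and
the standard errors of direct/indirect/total effects use the delta
method with numerical Jacobians. Fixed parameters carry no standard
error.

The saturated log-likelihood needed for chi-square testing is closed
form with complete data; under missingness the unrestricted multivariate
normal is fitted by EM (relative tolerance 1e−10) and the FIML
likelihood evaluated at the EM solution. The baseline (independence)
model separates by variable, so its FIML solution is the per-variable
univariate normal fit in either case.

## Testing, indices, pruning, decomposition

The test statistic is `T = 2(llₛₐₜ − llₘₒdₑₗ)`, clamped at zero, with
`df = p(p+3)/2 − q`. Incremental indices use the conventional
independence baseline: `CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0)`
and `TLI = ((T_b/df_b) − (T/df)) / ((T_b/df_b) − 1)` (raw TLI stored,
reported value clamped to [0,1]). `RMSEA = √(max(T−df,0)/(df·n))` with
the n (not n−1) denominator, switchable; its 90% CI inverts the
noncentral chi-square CDF (noncentrality with CDF 0.95 at T for the
lower bound, 0.05 for the upper). Adequacy labels: CFI/TLI adequate
above 0.90; RMSEA good at ≤ 0.05, adequate to 0.08, poor beyond.

Modification indices are 1-df score (Lagrange multiplier) statistics:
for each absent structural path among constructs and each absent
residual covariance among same-latent indicators, the gradient and
observed information of the augmented model are evaluated at the
restricted estimate (candidate at zero) and `g′ I⁻¹ g` is reported,
restricted to the original parameters plus the single candidate so the
statistic stays 1-df even when freeing the candidate would create
incidental free slots. Candidates that would break identification (e.g.
close a directed cycle) are skipped with a note. Indices are reported,
never auto-applied.

Backward pruning implements the p < 0.05 reporting rule: one path per
iteration — the prunable structural path with the largest p ≥ 0.05 — is
removed and the model refitted, warm-started from the surviving
estimates, until all remaining prunable paths are significant. Removing
one per iteration (rather than all at once) matters because p-values
shift after each refit. Loadings, covariances and paths from the
adjustment covariates (age, gender) are never pruned.

Direct/indirect/total effects use the matrix identity: total effects
among the variables are the off-diagonal entries of `(I − A)⁻¹`, the
direct effect is the entry of `A`, and the indirect effect their
difference — equal, on acyclic graphs, to the sum over all simple
directed chains of products of path coefficients (verified against
explicit path enumeration in the tests). `total = direct + indirect`
holds to machine precision by construction.

## The synthetic cohort generator

No subject-level data are distributed with the analysis, so the
generator is the package's ground-truth instrument. It reproduces the
study design exactly per cohort — 292 subjects (97 COPD / 96 smokers /
99 non-smokers), 103 women, per-variable observed counts (e.g. KCO 242,
telomere 265, cytokines 264) — and the published marginals and
standardized path coefficients as the generating truth.

Generation happens on a standardized scale. Exogenous design first: age
~ Normal(59.4, 7.3²); gender a 0/1 indicator with exactly 103 women;
pack-years zero in non-smokers and, in smokers, drawn from a normal
left-truncated at 10 pack-years (the study's smoker definition) whose
underlying location and scale are solved numerically so the truncated
distribution has mean 42.6 and SD 24.8 — the published moments describe
the observed smoker distribution, so they are matched after truncation,
not before. Each endogenous variable then follows its linear equation in
topological order with Normal(0, 1 − R²) residuals, where R² is computed
from the *analytically propagated* population covariance of its
predictors; this makes the configured standardized coefficients exact
population values rather than simulation-calibrated ones, and any
configuration whose equations imply R² ≥ 1 is rejected up front.
Finally, a presentation-only map puts variables on raw scales: affine
for age, FEV1 and KCO (means/SDs as published), exponential for the
log-scale variables with the log-location at the published median and
the log-scale matched to the published quartiles. Log-scale variables
are therefore strictly positive by construction, and the subsequent
log-transform in the pipeline returns an affine function of the
generated standardized variable, so standardized estimates are directly
comparable to the generating values.

Generating values: the published whole-sample standardized coefficients
are used verbatim for every printed path (e.g. FEV1→telomere 0.254,
smoking→WBC 0.288, FEV1→CRP −0.295, KCO→musculoskeletal 0.270); cells
reported non-significant are generated as true zeros, which makes the
sparsity of direct smoking effects (CRP, WBC, eGFR only) part of the
generating truth. Parameters the source tables do not print carry fixed
defaults, documented here and excluded from recovery claims:
smoking→FEV1 = −0.45 and smoking→KCO = −0.35; COPD-group shifts on lung
function (−0.35 / −0.25) so COPD patients sit lower on FEV1/KCO than
equally-exposed smokers and the PCA separates the three groups; age
effects ±0.20 on the musculoskeletal factor, PWV, telomere length and
eGFR, signed by physiology; gender (female)→musculoskeletal −0.25; all
factor loadings 0.75. The pulse-wave-velocity marginal is likewise not
published in the cohort table; a realistic aortic PWV distribution
(median 9.8, quartiles 8.3–11.6 m/s, 285 observed) is used and excluded
from marginal-calibration claims. The COPD-group indicator exists only
inside the generator — it is not a column of the modeled dataset — which
also means the fitted smoking→lung coefficients estimate the marginal
(exposure-plus-group) association, another reason those two paths are
outside the recovery contract. The published pack-years completeness
(186 of 193 smokers) plus the 99 known zeros gives the 285 observed
count used for that variable.

Missingness is MCAR with exact per-variable counts (uniform sampling
without replacement, independent across variables), since the source
reports only completeness, not a mechanism.

What the generator does *not* emulate: median/IQR shapes beyond the
two matched quantile pairs, MAR/MNAR missingness, measurement
heteroscedasticity by group, the binary nature of gender inside the
normal likelihood (gender is generated binary but modeled as an ordinary
exogenous variable — a standard, documented approximation), and any
longitudinal structure. Passing tests therefore demonstrate that the
engine recovers a known linear-Gaussian structure under the study's
design and missingness, not that the original clinical estimates are
correct.

## Model 1 specification choices

Candidate direct smoking→outcome paths start fully present and are
removed by the pruning rule, so "direct effects only for CRP and WBC"
can emerge as a data-driven outcome rather than an assumption. A free
residual covariance connects FEV1 and KCO: both are lung-function
measures and share group-level variance beyond pack-years; without it
the model family could not represent the generating covariance and
recovery of the printed paths would be biased. Whether the age/gender
adjustment paths should themselves face the p < 0.05 rule is not
settled; they are exempt here (they encode the design decision to
adjust, not hypotheses), and the pruner accepts any other choice via the
`prunable` flag on each path.

## Problem sizes and numerical choices in the test suite

The suite exercises the engine at sizes chosen for tight oracles at
desk scale: chi-square calibration uses 500 replicates of a 4-variable
model (statistic mean within 10% of df), type-I error of a true-zero
path 1000 replicates (rate 0.05 ± 0.02), modification-index null
calibration 120 replicates, parameter recovery 50 complete cohorts of
n = 2000. With 50 replicates the observed CI coverage moves in steps of
0.02, so the coverage band [0.90, 0.99] is tested by binomial
consistency (α = 0.01 per side) rather than on the raw proportion — a
perfectly calibrated 95% interval produces 50/50 hits in roughly 8% of
paths, which must not be read as over-coverage; a 250-replicate
calibration run gave per-path coverage between 0.936 and 0.984. Pruning
behavior at the study's own size (n = 292 with published missingness) is
checked qualitatively across seeds: surviving direct smoking paths are a
subset of the truly nonzero set {CRP, WBC, eGFR} in the majority of
seeds; at that sample size the weaker true paths (e.g. smoking→eGFR at
0.15) are regularly pruned for lack of power, exactly as expected.

## Known limitations

* Multivariate normality is assumed by the likelihood; binary gender and
  the zero-inflated pack-years variable violate it (coefficients remain
  the correct linear projections, but their SEs are mildly approximate).
* No robust (sandwich) or bootstrap standard errors; no ordinal
  indicators, multi-group estimation, or nonlinear paths.
* Modification indices for candidates near identification boundaries can
  be unstable; such candidates are skipped rather than regularized.
* The saturated EM fit assumes enough pattern overlap to identify the
  unrestricted covariance; pathological missingness designs (entire
  variable pairs never jointly observed) are not handled specially.
* Pruning is greedy (largest p first); with heavily correlated
  candidates a different removal order could retain a different set —
  the removal log makes the order auditable.
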