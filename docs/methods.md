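# Methods

## Statistical models

### Default Bayes factors

All hypothesis tests report BF₀₁, the marginal-likelihood ratio of the point
null to a default heavy-tailed alternative; BF₀₁ > 1 favours the null.
Following the usual reading guide, values in (1, 3] are weak and (3, 10]
moderate evidence toward the null, with reciprocal bands toward the
alternative.

**Two-sample test (JZS).** The model assumes a common variance with a
Jeffreys prior and a zero-centred Cauchy prior with scale r on the
standardised effect δ. The alternative marginal of the pooled t statistic is

m₁(t) = ∫ T_ν(t; δ√n_eff) · Cauchy(δ; r) dδ,  ν = n₁+n₂−2, n_eff = n₁n₂/(n₁+n₂),

and BF₀₁ = T_ν(t)/m₁(t). We evaluate the integral after substituting
δ = r·tan θ, which maps the domain to (−π/2, π/2) and keeps the integrand
bounded by the maximum of the noncentral-t density for *any* scale — in
particular the r → 0 limit, where BF₀₁ → 1, is numerically exact. The
equivalent representation of the Cauchy as a normal mixed over
g ~ Inv-Gamma(1/2, r²/2) is retained as an independent Monte-Carlo oracle in
the test suite; the two routes agree to 0.5% on a fixed grid of cases.
Although the accompanying frequentist check is a Welch test, the Bayesian
model pools variances; the study sample's variance ratio is close to 1
(F₆₅,₂₀ ≈ 1.05), so the distinction is immaterial here.

**Correlation test.** The prior on ρ is a stretched Beta(1/κ, 1/κ): a Beta
density linearly rescaled from (0, 1) to (−1, 1). κ = 1 gives the uniform
prior; small κ concentrates at 0. The likelihood is the exact sampling
density of the Pearson r under bivariate normality (Fisher's distribution in
its hypergeometric form), validated in the tests against the empirical
distribution of 10⁵ simulated samples. The alternative marginal is
integrated in the prior's CDF coordinate (ρ = 2·BetaInv(u) − 1, u ∈ (0, 1)),
which keeps the integrand O(1) and smooth even when the prior is a spike,
after factoring out the integrand's maximum on a coarse grid. Note that the
small-κ limit approaches 1 only once the prior sd (≈ √(κ/2)) falls below the
reciprocal of the log-likelihood slope n·r; at κ = 10⁻³ with n = 87 and
r = 0.3 the genuine BF₀₁ is ≈ 0.87, not 1.

**Regression.** Nested linear models are compared under Zellner's g-prior on
the non-intercept coefficients with g ~ Inv-Gamma(1/2, rate). The marginal
likelihood ratio of a k-covariate model to the intercept-only model is

BF₁₀ = ∫ (1+g)^((n−1−k)/2) (1 + g(1−R²))^(−(n−1)/2) π(g) dg,

a function of (n, k, R²) only. The rate is n·r²/2 by default (the
Zellner–Siow convention of the reference software family) with the literal
r²/2 available via a flag; the default is the convention that reference
implementations use and is what the sensitivity endpoints imply. The
integral is computed in the scale-free coordinate z = g/rate (z is then
Inv-Gamma(1/2, 1) regardless of the scale), with the log-integrand's maximum
factored out to avoid overflow at large n or R². Nested comparisons divide
two such BF₁₀ values; the all-subsets model search enumerates all 2^p
covariate subsets, flags rank-deficient designs rather than dropping them,
and sorts by BF₁₀ with lexicographic tie-breaking. Binary covariates enter
as centred 0/1 columns under the same prior.

**Prior scales.** Medium-width defaults throughout: Cauchy r = √2/2,
κ = 1/3, regression r = √2/2. Sensitivity curves vary κ over [0.001, 1] and
the Cauchy scale over [0.001, 1.5] and flag the medium operating point.

### Classical sanity checks

Pearson correlation with a two-sided t-transform p and a Fisher-z interval
tanh(atanh r ± z/√(n−3)); Welch two-sample t with Satterthwaite df and a CI
for the mean difference; variance-ratio F with two-sided p by doubling the
smaller tail (the convention consistent with p ≈ 0.94 at F ≈ 1). Missing
values are rejected, never silently dropped — exclusion is an explicit
upstream step with a logged reason per row.

### Framingham 10-year risk

The lipid-based general-CVD survival model: risk = 1 − S₀^exp(L − L̄) with a
sex-specific linear predictor in ln age, ln total cholesterol, ln HDL,
ln SBP (separate coefficients for treated/untreated), current smoking and
diabetes. Coefficients are stored in a checksummed JSON data file and
validated in the tests against the source's published worked example
(10-year risk 10.5% for the reference female profile). Conditions resolve
with the precedence medication-use → self-reported diagnosis → measurement
threshold (SBP ≥ 130 or DBP ≥ 80; glucose > 125, strict; total cholesterol
≥ 200); a missing antihypertensive answer is read as untreated, any other
unresolvable case is an error rather than an imputation. Risk is kept as a
probability in (0, 1). MAP uses the standard one-third pulse-pressure
formula DBP + (SBP − DBP)/3.

### PCA vascular score

Correlation-matrix PCA (z-scored inputs — the eight indicators have
incommensurate units) on BMI, MAP, HDL, LDL, total cholesterol,
triglycerides, fasting glucose and a current-smoker 0/1 indicator treated
like the continuous columns. Loadings carry a deterministic sign convention
(largest-magnitude entry positive), making refits on permuted rows
identical. Split-sample replication uses a 50/50 random partition with a
caller-supplied seed and Tucker's congruence per component, with 0.9 as the
"replicated" label; new subjects are projected with the *training* means
and SDs. These replication details are design choices of this package.
Component matching across splits is by eigenvalue rank, so near-degenerate
eigenvalues can legitimately produce low congruence.

### Bayesian power

Power is the probability that BF₀₁ crosses a threshold under a true effect:
BF₀₁ ≤ 1/3 counts as support for the alternative, BF₀₁ ≥ 3 as support for
the null, and the band between is inconclusive (so the two probabilities can
sum to less than 1). The two designs are 66 + 21 subjects with a
standardised mean difference of 0.5 (pooled t inside the simulation,
matching the Bayesian model), and 87 bivariate-normal pairs with unit
variances and ρ = 0.3. Default 10⁴ replicates with binomial Monte-Carlo
standard errors reported alongside; the replicate count is a parameter.

An exact semi-analytic benchmark exists because BF₀₁ is a deterministic
monotone function of |t| given the group sizes: the power equals a
noncentral-t tail probability at the critical t where BF₀₁ crosses the
threshold. For the 66/21, d = 0.5, r = √2/2 design this gives
P(BF₀₁ ≤ 1/3) = 0.338 and P(BF₀₁ ≥ 3) = 0.112 (critical t 2.429 and 0.791
at ν = 85). The correlation design gives ≈ 0.70 and ≈ 0.02.

### Synthetic cohort

The generator emulates the study sample's structure: exact category counts
(51 female / 36 male, 21 amyloid-positive, 23 ε4 carriers out of 87), age
from a truncated normal calibrated to median 77 and IQR 70–83, vascular
variables from a Gaussian copula with plausible pairwise correlations
(positive adiposity–pressure–glycaemia block, negative HDL–triglycerides),
smoking category frequencies 55/31/1 per 87, and self-report flags loosely
consistent with the measurements (70–80% medication rate among diagnosed,
10% report noise, 5% missingness). Amyloid DVR is a two-component normal
mixture, N(0.98, 0.045²) and N(1.28, 0.10²), straddling the 1.06 positivity
cutoff; group labels come from the true component. Tau SUVR is linear in
DVR (slope chosen so the amyloid-group difference is the configured 0.09)
plus noise; the log WML/WMV ratio and the SUVR noise are tied to the
*computed* Framingham risk of the generated subjects — risk is never drawn
directly, so vascular variables and risk stay mutually consistent — with
the configured correlations (0.24 for lesion burden; 0 by default for
SUVR, the null scenario). Because the risk-linked share is computed against
the realised risk distribution, configured correlations hold in expectation
over cohorts, not exactly per draw.

What the generator does **not** emulate: the real sample's joint
distribution (the copula values are invented), longitudinal structure,
scanner effects, or any outlier mechanism. Passing tests therefore
demonstrate correctness of the *procedures* under a known generative truth,
not properties of any real cohort.

### GMM cutoff and harmonisation

The amyloid positivity threshold fits a two-component univariate Gaussian
mixture by EM (10 restarts) and takes the point between the ordered
component means where posterior membership probabilities are equal (for
equal weights this is the density crossing); degenerate fits and missing
crossings are errors. Scanner harmonisation is OLS of one scanner's values
on the other's, returning slope, intercept and an apply function.

## Numerical choices

- Adaptive quadrature (QUADPACK) everywhere, absolute tolerance 1e−12 and
  relative 1e−10, with the quadrature error propagated to a relative error
  estimate on the result; a result whose estimated relative error exceeds
  1e−6 raises rather than returning silently.
- Integrands are evaluated as exp(log f − max log f) with the maximum found
  on a coarse grid, so large-n regressions and spiked priors cannot
  overflow or vanish.
- Noncentral-t density overflows at extreme noncentrality (a library
  limitation) are treated as numerically zero density, which is correct in
  that regime.
- R² from least squares is clipped to [0, 1 − 1e−12]; risk probabilities to
  (1e−12, 1 − 1e−12).
- Simulation sizes in the test suite: 10⁴ replicates for power and
  calibration checks, 10⁵ for distributional (KS) checks, 100 seeded
  cohorts for recovery checks — chosen to make Monte-Carlo error small
  relative to the asserted tolerances.

## Known limitations

- Two-sided tests only; no posterior effect-size estimation, no Bayesian
  ANOVA with factor-specific scales.
- The t-test power of the 66/21 design is genuinely 0.34/0.11 at the stated
  thresholds (see the semi-analytic benchmark above); an equal 44/43 split
  of the same 87 subjects gives ≈ 0.45/0.08. Reported power figures should
  always be read against the exact group sizes used.
- The office-based (BMI) Framingham variant, pooled-cohort equations, and
  30-year horizons are out of scope.
- The PCA replication criterion (split fraction, seed policy, congruence
  threshold) is a package design choice, not an estimate of any published
  procedure.
- No multiple-testing adjustment anywhere, by design.
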