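# Methods

## The problem

A variance QTL (vQTL) is a genetic variant whose genotype groups differ in
phenotypic *variance* rather than (or in addition to) phenotypic mean.
Gene-by-environment (GxE) interaction is a canonical generator of such
signals: if an exposure modifies the genotype effect, individuals carrying
the interacting allele spread out more.  vqtlbench compares ten published
vQTL detection methods under a common generative model, measuring their
false positive rate (FPR) and power by Monte Carlo simulation, and provides
a matrix-scale scan for applying the winning tests to genotype x phenotype
matrices.

## Generative model

One biallelic locus with minor allele frequency (MAF) p, genotype coded
g in {0, 1, 2} (minor allele count), group sizes at Hardy-Weinberg
proportions ((1-p)^2, 2p(1-p), p^2).  The trait is

    y = a_mean * G + a_env * E + a_var * (G x E) + a_error * error

where each of the four component vectors — genotype codes, exposure codes,
their elementwise raw product, and an error draw — is min-max normalized
to [0, 1] *before* weighting, and the nonnegative weights sum to one
(`a_env` is implicit).  Defaults follow the study conditions: a_error =
0.2, MAF 0.05, n = 1,000 for the main comparisons.  Exposures are binary
(default 10% exposed), uniform(20, 70) or normal(25, 3); errors are
standard normal, chi-squared(df = 1) or gamma(shape 2, rate 0.5) — the
error scale is irrelevant because of the min-max step, only its shape
matters.  A genetically associated exposure variant replaces E by
E1 = E + a_mean * g on raw scales.

### Variance-only designs

A GxE product term shifts group means as a side effect: the expected mean
of the interaction term in genotype group g is g times the
exposure-weighted mean of the exposure codes.  For a binary exposure with
exposed fraction f the codes ((1-f)/f, -1) zero that weighted mean, so the
expected trait mean is identical in all three genotype groups and any
detection is a pure variance signal.  At f = 0.1 the codes are (9, -1); at
f = 0.5, (1, -1).  Binary assignment uses exact counts (round(f*n) exposed,
randomized order), so the stated proportions hold exactly; continuous
exposures are i.i.d. draws and their category proportions are not
controlled.  Variance-only designs are only constructed for binary
exposures; continuous-exposure power settings use a_mean = 0 but accept the
residual mean shift from the product term (the two-stage and
median-distance tests are insensitive to it).

### Genotype group sizes

Every genotype class must contain at least `min_group` (default 10)
samples, to keep the variance estimates in the minor-homozygote group
meaningful and to avoid spurious signals from near-empty groups.  The
default sampling mode fixes class sizes at their rounded Hardy-Weinberg
expectations, floored at `min_group` (the deficit is taken from the
largest class), and shuffles the class labels: n and MAF determine the
group sizes, and the constraint holds by construction even where the HWE
expectation is below the floor (n = 1,000 at MAF 0.05 expects 2.5 minor
homozygotes and is floored to 10).  A `multinomial` mode draws class sizes
multinomially and rejection-resamples whole vectors up to a cap (default
1,000 attempts), raising with the expected minor-homozygote count on
failure; it is only feasible where n * MAF^2 is not far below the floor.

### Degenerate inputs

Min-max of a constant vector returns zeros (not an error), so scenarios
with a zero weight degrade gracefully.  Tests that hit a degenerate stage
(constant distances, zero stage-1 residual variance, tied normal scores)
return p = 1 with a note and are counted as non-discoveries, never as
rejections.

## The ten methods

* **Levene / BF** — one-way ANOVA on distances |y - center(group)|, center
  = mean (Levene) or median (Brown-Forsythe); F with (G-1, N-G) df.
* **Bartlett** — log-ratio of pooled to group variances with the standard
  small-sample correction; chi-squared, G-1 df.
* **FK** — modified Fligner-Killeen: median-centered distances ranked
  across all samples, mapped through Phi^{-1}(1/2 + r/(2(N+1))); group
  score means vs overall score variance; chi-squared, G-1 df.  Average
  ranks for tied distances.
* **SVLM** — stage 1: OLS y ~ 1 + g (+ covariates); stage 2: OLS of the
  squared stage-1 residuals on 1 + g; Wald t of the genotype slope.
* **CLS** — Spearman correlation of squared stage-1 residuals with g;
  p from t = rho * sqrt((n-2)/(1-rho^2)), a choice documented here because
  the exact-permutation alternative is not stated in the source method.
* **DRM** — OLS of |y - median(group)| on 1 + g; Wald t.
* **Z-score** — rank-based inverse normal transform of y, squared,
  regressed on 1 + g.  Included as a cautionary method: the transform
  induces mean-variance coupling.
* **QUAIL** — quantile-integral model.  For tau_k = k/(K+1) (K = 100 by
  default, even so levels pair across 0.5), the quantile rank score
  a_tau(i) = tau - 1{y_i <= Q_tau} is computed at each level from the null
  conditional quantiles (empirical quantiles with no covariates, per-tau
  quantile regressions otherwise), and the per-sample integrated score
  s_i = mean_{tau<0.5}(a_{1-tau}(i) - a_tau(i)) — a Riemann approximation
  of the integral of beta_{1-tau} - beta_tau — is regressed on genotype.
  The slope is the integrated quantile effect estimate and its Wald t the
  p-value; a genotype-permutation fallback (default 200 permutations) is
  available.  Because the score is a rank functional of y, the test is
  distribution-free under an exchangeable null, which is why it stays
  calibrated under skewed errors here.
* **DGLM** — double generalized linear model.  Alternate weighted least
  squares for the mean submodel (weights 1/phi_i) with a gamma log-link
  GLM for the dispersion submodel: leverage-corrected squared residuals
  e_i^2/(1-h_i) on 1 + g with prior weights (1-h_i)/2, the standard
  double-GLM construction; gamma dispersion fixed at its asymptotic value
  2 (folded into the prior weights, GLM scale 1).  Iterate until the
  dispersion deviance changes by < 1e-8 (max 50 iterations); Wald test of
  the genotype coefficient in the dispersion submodel.  Non-convergence is
  reported (converged = False, p absent) and excluded from rate
  denominators.

Preprocessing: the trait is residualized on the exposure before testing
(OLS), except for SVLM and CLS whose own stage-1 regression absorbs the
exposure together with genotype.  The unobserved-exposure variant skips
the adjustment entirely.  The rank-INT route (offset (r - 0.5)/n; Blom
offset available) is applied only in the normalization-inflation
experiment and never to the Z-score test.

## Monte-Carlo engine

`run_grid` estimates one rejection rate per (scenario, method) cell at
alpha = 0.05 (inclusive, p <= alpha).  The seed of replicate r of scenario
s is SeedSequence([master, crc32(s), r]) truncated below 2^31 — a pure
function of the triple, so any cell is reproducible in isolation and the
result is independent of execution order.  Rates come with the binomial
Monte-Carlo standard error sqrt(r(1-r)/R); statistical assertions in the
test suite use the band +/- max(0.03, 3 * sqrt(r(1-r)/R)).

Problem sizes: the main null calibration uses 1,000 replicates at
n = 1,000; power runs use 500 replicates up to n = 10,000 and 200
replicates at n = 200,000; the inflation and monotonicity experiments use
100-200 replicates.  These sizes put every Monte-Carlo standard error at
or below ~0.035 while keeping a full benchmark run in the minutes range.

## Matrix scan

`vqtl_scan` filters variants (MAF floor and >= `min_group` samples per
genotype class, skipped variants logged with reasons), tests every
(feature, variant, method) triple, and estimates the FDR by re-running the
scan on phenotype matrices whose sample labels are permuted against the
whole genotype matrix (20 permutations by default), preserving
inter-variant LD.  FDR(t) = (mean permuted discoveries at p <= t) /
(observed discoveries at t), clipped to [0, 1] and enforced monotone
non-decreasing in p (step-up).  The FDR is estimated per feature by
default, with a flag for a single global estimate.  The epistasis check
fits y ~ g1 + g2 + g1*g2 (+ covariates) and Wald-tests the product term.

## What the simulations do and do not show

The generator reproduces the structure the benchmark is about — a single
interacting locus, one exposure, controlled effect weights, controlled
error shapes — and the conclusions (which tests are calibrated and
powerful under which distributions) are statements about that structure.
Real data add linkage disequilibrium between variants, hidden
mean-controlling QTLs in LD with the tested variant, relatedness between
samples, multi-exposure interactions and parent-of-origin effects, none of
which are modeled; family-structure corrections and LD-aware follow-ups
are out of scope.  Passing tests therefore demonstrate correctness of the
methods and of the engine under the stated model, not robustness to those
real-data complications.

## Design choices that were genuinely open

* Group sizes at HWE expectations with a floor (default) vs multinomial
  with rejection: the expected-count mode is the only one feasible at the
  flagship n = 1,000 / MAF 0.05 setting; both are provided.
* The interaction uses the coded minor-allele count g by default;
  `interact_flipped` interacts with 2 - g instead.  Min-max normalization
  absorbs affine recodings of the standalone genotype term, so the flag
  only affects the interaction term's group labeling.
* QUAIL's significance construction: integrated rank-score regression
  (default) with a permutation fallback; the integrated effect is
  estimated from the rank-score slope rather than by averaging K separate
  quantile-regression fits, which is both the aggregation the original
  estimator uses and orders of magnitude faster in the no-covariate case.
* CLS uses the t-approximate Spearman p-value.
* Rank-INT offset (r - 0.5)/n, with Blom as a sensitivity option.
* DGLM replicates that fail to converge are excluded from rate
  denominators and reported separately.
* Permutation FDR is estimated per feature by default (`per_feature`
  flag), since thresholds are feature-specific in expression scans.

## Known limitations

* The dispersion-model Wald test in DGLM relies on the asymptotic gamma
  dispersion of 2; at very small group sizes this is approximate (the
  calibration suite bounds the consequence at n = 1,000).
* The QUAIL covariate path fits 2 x K quantile regressions per call and is
  correspondingly slow; the benchmark routes covariates out beforehand.
* `vqtl_scan` is a straightforward nested loop — adequate for candidate-
  region scans, not engineered for genome-wide matrices.
* The min-group floor at rare MAF deliberately distorts HWE proportions
  (that is its purpose); MAF estimates from floored cohorts are slightly
  biased upward at small n.
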