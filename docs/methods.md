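# Methods notes

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `numsense`.  It is written for a user
who wants to understand what the package computes and what passing its
tests does and does not establish.

## 1. The categorization task and its observer model

The task briefly presents (500 ms, too short to count) a field of 8–32
dots and asks for a binary "few"/"many" categorization.  Eleven test
numerosities are log-uniformly spaced over the two octaves around 16
(8, 9, 11, 12, 14, 16, 18, 21, 24, 28, 32; integer-rounded half away from
zero so the printed ladder is reproduced exactly).  Four unscored anchor
trials showing the extremes precede testing; we fix their order to
max–min–max–min so both extremes are exposed as early as possible, and
anchor trials never enter any fit.  Each test level appears `reps` times
(default 4, i.e. a 44-trial session) in a seeded uniform random order.

Dot fields are generated by rejection sampling inside a 12°-diameter
virtual circle: dot centers stay one dot radius inside the rim and at
least one dot diameter apart (no overlap), with a per-dot retry cap of
10,000.  Polarities are split as evenly as possible between white and
black to balance luminance.  Coordinates are degrees of visual angle with
the origin at the field center; no rendering is performed.

The observer model is a cumulative Gaussian on log10 numerosity with an
optional lapse rate:

    p(many | N) = lapse/2 + (1 − lapse) · Φ((log10 N − log10 PSE) / σ),
    σ = log10(1 + Wf) / z75,   z75 = Φ⁻¹(0.75) ≈ 0.67449.

The σ↔Wf mapping is chosen so that p(many) at N = PSE·(1+Wf) is exactly
75% when lapse = 0; Wf = 0 is handled as the step-function limit.  The
lapse default is 0 throughout (the analysis model has no lapse parameter
either, so generator and fitter are matched).

## 2. Psychometric fitting

Fits maximize the Bernoulli likelihood of the raw trials (not least
squares on binned proportions), over (μ, σ) with bounds
μ ∈ [log10 4, log10 64] and σ ∈ [10⁻³, 1] log10 units.  The likelihood
depends on the data only through per-level counts, so it is evaluated on
the binned representation for speed — this is an algebraic identity, not
an approximation.  Optimization is L-BFGS-B from five starts (three
data-informed, the rest seeded uniform draws in the box); ties are broken
by higher log-likelihood, then smaller σ.  A fit is flagged
`converged=False` when the optimizer fails or the winning estimate sits on
a parameter bound (e.g. the noiseless step-data limit, where σ pins to its
lower bound).  Standard errors come from a finite-difference observed
information matrix and are NaN on bounds.

Derived indices: PSE = 10^μ; JND = z75·σ (log10 units);
Wf = 10^JND − 1 = N75/N50 − 1.  We take the JND literally as the 50%→75%
distance because Wf = 10^JND − 1 is only dimensionally coherent for a
log-unit JND.  A common alternative convention takes the JND as σ itself;
the two differ by the constant factor z75, so Weber fractions under the
other convention are obtained by replacing z75 with 1 in the mapping.
This convention choice rescales all Weber fractions by a constant and
therefore does not affect group comparisons or correlations.

Group "aggregate" fits pool all scored trials of a group's participants
and fit once, mirroring the standard aggregate psychometric-function
figure.

Estimator quality at the session budget (verified in the test suite): with
40 reps/level, 200 simulated observers with Wf ~ U[0.05, 0.45] are
recovered with |mean signed error| ≤ 0.02 and Kendall τ(ŵf, wf) ≥ 0.8; at
the 44-trial budget a Wf = 0.30 observer is noisy per session but the
median estimate over 500 replicates stays within ±0.05.

## 3. The synthetic cohort generator

The generator emulates a two-group clinical study (ADHD vs neurotypical
controls, default n = 20 per group, ages uniform on 8–16 years) whose
group-level moments are the package defaults:

* Weber fraction: normal with (mean, sd) = (0.177, 0.09) for ADHD and
  (0.143, 0.07) for controls, truncated below at 0.01.  Truncation yields
  the mild positive skew typical of threshold samples.
* PSE: normal with (15.63, 2.38) and (14.76, 1.97), truncated to
  [10, 26].  The truncation encodes that anchoring keeps subjective
  midpoints well inside the presented range — without it, a rare extreme
  PSE draw (≈1 in 1,500 observers) produces an all-"many" or all-"few"
  session with no finite psychometric MLE, a degenerate observer the task
  design is specifically built to prevent.  The bounds sit far outside the
  observed PSE range (≈11.5–19.5), so the configured moments are
  essentially unchanged.
* Sex: fixed splits of 14 M / 6 F (ADHD) and 9 M / 11 F (controls),
  scaled proportionally for non-default group sizes.
* Six math tasks: per-task z-scores are drawn as
  z = m_task + s_task·(√w·f + √(1−w)·ε), where f is a per-participant
  common factor and w = 0.25 the within-battery loading.  The loading was
  set from the configured moments themselves: given the per-task SDs, w =
  0.25 makes the implied SD of the six-task mean match the configured
  aggregate-index SDs (≈0.71 ADHD / 0.58 controls).  Raw scores are
  produced by inverting the normative table, so z-scoring them recovers
  the generated values exactly.
* Wf–math link: a Gaussian copula ties the battery factor f to −Wf with
  copula correlation sin(π·ρ/2), ρ = 0.3 on Kendall's scale.  The realized
  Wf–aggregate rank correlation is attenuated below ρ by the task-specific
  noise (≈0.8 of it at w = 0.25); the link exists so the correlation stage
  has a known qualitative target (negative association), not a calibrated
  magnitude.
* Missingness: per-task per-group counts of absent raw scores are
  configured, not sampled, so they are identical across seeds (defaults:
  2/2/2/1/1/2 for ADHD, 0/0/0/1/1/2 for controls).  One ADHD participant
  misses the entire battery; remaining missing slots are concentrated
  greedily on as few participants as possible (at most two tasks each), so
  the default control pattern is one 4/6 completer and two 5/6 completers.
* Clinical scores (ADHD only): a parent-rating index as T-scores
  N(60, 10); a clinician severity rating as integers 1–7 (rounded
  N(4.5, 1), clipped); a global-functioning severity *category* 1–10
  (rounded N(5, 1.5), clipped).  No correlation with Wf is generated.
* Nonverbal reasoning z-scores: N(−0.15, 0.9) for ADHD (4 participants
  missing, mirroring unavailable composite scores) and N(0.42, 0.95) for
  controls.

What the generator does **not** emulate: response-time structure,
within-session learning or fatigue, age trends in Wf (draws are
age-independent, so developmental-trajectory analyses on synthetic data
are null by construction), non-normal score distributions beyond what
truncation induces, and any subscale structure of the nonverbal battery.
Passing tests on synthetic cohorts therefore establishes that the
*pipeline* is correct and well calibrated under its assumed model — not
that the assumed model captures every feature of real clinical data.

## 4. Bayes factors

All evidence is reported as LBF = log10 BF₁₀, with the conventional
reading (substantial > 0.5, strong > 1, definitive > 2; the boundaries
themselves count as inconclusive — strict inequalities).

**Two-sample t-test (JZS).** Cauchy(0, r) prior on the standardized effect
(default r = 0.707), written as the normal/inverse-gamma mixture
δ | g ~ N(0, g), g ~ InvGamma(½, r²/2).  The Bayes factor is a single
integral over g, computed by adaptive quadrature on u = g/(1+g) after
rescaling by the integrand's peak.  Verified against a 10⁵-point trapezoid
oracle to |Δlbf| < 10⁻³.

**Rank-based two-sample test.** Only the pooled ranking enters.  Latent
normal values consistent with the observed ordering are Gibbs-sampled
(even/odd rank positions are conditionally independent given their
neighbors, so each half-sweep is vectorized) together with a standardized
group offset δ under the same Cauchy prior.  BF₀₁ is the Savage–Dickey
ratio at δ = 0 with the posterior ordinate Rao-Blackwellized over sweeps;
a batch-means Monte Carlo SE is reported.  Validity is checked against an
*exact* small-n oracle: the probability of the observed ordering under
shifted normals is computed by sequential one-dimensional integration and
integrated over the prior.  Ties are broken by stable sort order; with
heavily tied data the rank likelihood is only approximate.

**Pearson correlation.** Stretched-beta prior on ρ (width 1 = uniform on
(−1, 1)), with the exact sampling density of the sample correlation
r | ρ, n (hypergeometric form) as likelihood; one-dimensional quadrature.
Perfectly collinear data (|r| = 1) makes that density degenerate; r is
clamped at 1 − 10⁻⁴ and the returned (large) evidence is then a lower
bound.

**Kendall correlation.** τ_b is standardized by its null SE,
se = √(2(2n+5)/(9n(n−1))); given a population τ the standardized statistic
is asymptotically N(1.5·τ·√n, 1).  A stretched-beta prior sits on τ and
the BF is the marginal-to-null likelihood ratio (equivalently the
Savage–Dickey ratio).  The statistic itself is cross-checked against an
exhaustive pair-counting implementation for small n.  The asymptotic
likelihood is an approximation; at n ≲ 10 its BFs should be read as
indicative.

**ANCOVA inclusion.** For a dependent variable with a two-level group
factor and numeric covariates, every additive subset of terms is scored
against the intercept-only model.  The group contrast is coded ±½ and
scaled by r_fixed (default 0.5); covariates are standardized and scaled by
r_cov (default 0.354 = 0.5/√2); coefficients share one g with
g ~ InvGamma(½, ½) (a Zellner–Siow setup with per-term scales folded into
the columns), so each model's marginal likelihood is a one-dimensional
quadrature.  With equal prior model probabilities the inclusion BF of a
term is the ratio of summed posterior model probabilities with versus
without it.  In an additive-only model space this "across all models"
inclusion BF coincides algebraically with the matched-models variant
(every model containing a term is a model without it plus the term), so a
separate option would be vacuous.  Complete cases are used listwise per
dependent variable; rank-deficient designs raise an error naming the
offending columns.  Covariates are always standardized internally as part
of the prior scaling, which also settles whether to standardize them: the
inference is invariant to their original units.

**2×2 contingency.** Gunel–Dickey independent-multinomial Bayes factor
with symmetric Dirichlet(a) priors (default a = 1), rows treated as the
sampling groups with fixed totals.  Under the null the common column
vector carries the adjusted concentration Σᵢa − (r−1), which remains a for
a = 1.  Closed form in gamma functions; verified against direct numerical
integration of binomial likelihoods.  A one-sample Dirichlet–multinomial
test of counts against fixed expected proportions is provided separately
(`lbf_multinomial`), since "multinomial test" in GUI statistics software
usually denotes that one-sample form; the two can differ materially on the
same data.

**Power analysis.** Exact noncentral-t power for the equal-n two-sample
t-test (noncentrality d·√(n/2), df = 2n−2); required sample size is the
smallest n ≥ 2 reaching the target power.  At d = 1.2, α = 0.05, power
0.95 two-tailed this gives n = 20 per group (power 0.949 at 19, 0.959 at
20), verified against 20,000-replicate simulation.

**Descriptives and assumption gate.** Descriptive tables use the sample SD
(n−1), bias-corrected skewness G1 and bias-corrected excess kurtosis G2 —
the conventions of mainstream GUI statistics software.  Group comparisons
are gated by Shapiro–Wilk on each group (α = 0.05): the rank-based test is
selected as soon as either group rejects normality, and the W statistics
and p-values are recorded in the report as the selection trace.

## 5. The pipeline

`run_study` executes: load/simulate → per-participant psychometric fits
(participants shipping precomputed Wf/PSE skip fitting, supporting
deposit-style per-participant data) → normative z-scores and aggregate →
demographics (age t-test BF, sex contingency BF) → normality-gated group
comparisons for Wf, PSE, the aggregate and each task → within-group
Kendall correlation of Wf with the aggregate → ANCOVA inclusion BFs for
the "impaired" measures (group-comparison LBF > 1, plus the aggregate
always) with covariate sets {Wf} and {Wf, nonverbal reasoning, age, sex} →
clinical-scale Kendall correlations within the ADHD group (raw
global-functioning scores above 10 are first recoded to the 1–10 severity
categories; scores already ≤ 10 are assumed categorical) → a JSON report
plus CSV tables.  Every run is deterministic given the config seed
(sampler seeds are derived from one generator), and the report JSON is
byte-stable.

The aggregate math index is the mean of the available per-task z-scores,
defined only when at least `min_tasks` = 4 of 6 are present (a 4/6
completer keeps an aggregate; the all-missing participant has none and is
excluded from math analyses while remaining in the numerosity analyses).
Group-mean imputation is available as a robustness check and leaves
per-task group means unchanged by construction; the exact imputation
scheme used alongside the original study is not documented, so group-mean
imputation is our default choice and is off unless requested.

## 6. Known limitations

* The Kendall and rank-based Bayes factors rest on asymptotic or
  augmented likelihoods, not exact finite-sample distributions.
* The ANCOVA prior uses a single shared g per model; software that assigns
  independent g blocks per effect will produce (slightly) different
  inclusion BFs, especially with many covariates.
* The normality gate is itself a pretest; its type-I behavior is inherited
  by whichever test is selected.  The gate and both branches are reported
  so a reader can recompute either branch.
* Synthetic cohorts are age-stationary (see §3), so age-trend analyses are
  only smoke-tested.
* Evidence about a group-by-sex association depends strongly on the
  assumed sampling scheme — a one-sample multinomial test of pooled counts
  against fixed proportions and an independent-multinomial contingency
  test can disagree in sign on the same 2×2 table.  Both constructions are
  exposed (`lbf_multinomial`, `lbf_contingency_2x2`) so the analyst can
  state which sampling model they intend.
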