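# Methods

This note documents the statistical model behind `ftdpls`, the conventions
and defaults that matter for interpreting its output, what the synthetic
cohort generator does and does not emulate, and the design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Two-block PLS

Given a cognition block X (n × p_x) and a brain block Y (n × p_y), both
z-scored column-wise (unbiased SD, divisor n−1), the cross-block
correlation matrix R = XᵀY/(n−1) is decomposed by SVD, R = U Δ Vᵀ. Each
latent variable (LV) k pairs a cognition salience u_k with a brain salience
v_k; the covariance explained d_k²/Σ_j d_j² is its effect size and is
always computed over the full rank before any truncation, so retained-LV
effect sizes never depend on how many LVs a caller keeps.

The (n−1) divisor is a convention, not a substance choice: it leaves U, V
and the covariance-explained fractions unchanged but fixes the identity
cov(X u_k, Y v_k) = d_k (sample covariance, same divisor), which the tests
use to tie the decomposition, effect sizes and subject scores together.

**Permutation test.** The rows of X are permuted (default 500 times),
breaking the subject pairing while preserving each block's internal
covariance; the permuted singular values form the null, compared
rank-to-rank. P-values use add-one smoothing, p = (1 + #{d_perm ≥
d_obs})/(n_perm + 1): a finite test cannot certify p = 0. Rank-wise
singular values are the default statistic; a covariance-explained-fraction
statistic is available behind a flag, but note it is a *relative* measure —
under permutation the total cross-block covariance collapses, so fractions
are not comparable between observed and permuted decompositions and the
test loses power with several coexisting signals. LVs are "retained" when
their permutation p < 0.05, unadjusted.

**Bootstrap ratios.** Subjects are resampled with replacement jointly
across blocks (default 500 resamples, unstratified; stratified-by-group
resampling behind a flag), blocks are re-z-scored within each resample and
the SVD recomputed. Each resample's LVs are sign-aligned to the original
fit by the sign of ⟨[u_b; v_b], [u_0; v_0]⟩; no Procrustes rotation is
applied, so in near-degenerate spectra axis rotation between resamples
inflates bootstrap SEs — a known limitation of sign-only alignment.
BSR(variable, k) = original weight / bootstrap SD of that weight, and the
95% criterion flags |BSR| ≥ z_0.975 ≈ 1.96. Resamples that zero out a
column's variance are redrawn (bounded retries).

**Scores.** score_x = X u_k and score_y = Y v_k for any rows standardized
compatibly with the fit — follow-up visits are standardized with the
*baseline* means/SDs so their scores live on the baseline scale. Scores
are named by block (the cognition-block score is score_x), and pipeline
reports map "brain score" to score_y; reports never rely on which block an
equation label happened to call "brain".

Degenerate spectra: ties in d are broken by input column order (tolerance
1e−12); with tied singular values individual saliences are not identified,
only their span.

## Preprocessing

- **Imputation** is restricted by default to education — a covariate, not
  an outcome — and fills a missing cell with the mean of the observed
  values in the row's diagnostic group. Groups with no observed value are
  an error rather than a silent fallback.
- **Complete-case filtering** drops rows missing any cognition or covariate
  value and reports exclusions per group and per column; follow-up rows
  whose baseline was excluded are dropped too, keeping the
  baseline-linkage invariant.
- **w-scores** regress each variable on age, sex (encoded F=0/M=1) and
  education in controls only; a patient's w-score is (observed −
  predicted)/SD(control residuals) with the OLS residual standard error
  (divisor n_controls − p − 1). Controls therefore score ~N(0, 1) by
  construction. The pipeline defaults to z-scoring raw values and offers
  w-scoring as a sensitivity analysis (flag), since normative adjustment
  is a robustness check of the main analysis, not part of its definition.
- Multiple follow-up visits per subject are reduced to the one closest to
  the one-year target before analysis.

## Variant contrasts

Per retained LV, the moderated regression
`score_x ~ score_y + variant + score_y:variant` is fitted by OLS with
dummy-coded variant (three levels, each with ≥ 3 members required). All
three pairwise intercept and slope differences are extracted as linear
contrasts of the coefficient vector, which makes the results invariant to
the choice of reference level by construction (verified to 1e−8 in tests).
Tests are two-sided; the FDR family is the six contrasts (3 pairs ×
{intercept, slope}) within one LV, adjusted by Benjamini–Hochberg per LV.
The family definition is a choice — contrasts are reported per LV, so the
correction matches the reporting unit.

## Subtype classification

The learner is a pooled-covariance Gaussian linear discriminant written
out explicitly: class means, empirical class priors, pooled within-class
covariance (divisor n − K), discriminant scores δ_c(x) = xᵀS⁻¹μ_c −
½μ_cᵀS⁻¹μ_c + log π_c. When S is numerically singular a ridge of
1e−6·trace(S)/p is added — needed for small training folds. The ensemble
bags B = 100 such learners (a common bagging default; configurable), each
trained on a with-replacement resample of the training fold; draws missing
a class are redrawn. Prediction is the majority vote; vote ties go to the
class with the highest mean posterior across learners, then lexicographic
order — a fully specified, deterministic rule.

**Evaluation.** Stratified k-fold (default 10) cross-validation repeated
(default 100 times) with fresh partitions; stratification is required
because the smallest class has ~30 members. Accuracy is pooled over the k
test folds within a repeat; means and SDs are over repeats, never over
folds. Per-class metrics are one-vs-rest sensitivity and specificity, with
balanced accuracy their mean — exactly, not approximately, which the
acceptance suite checks as an accounting identity.

**Leakage policy.** In the default protocol the PLS is fitted once on all
baseline patients before cross-validation. Diagnostic labels never enter
the PLS or the standardization, but the test subjects do participate in
that unsupervised step; a nested mode (`cv_repeated_nested`) refits
standardization and PLS inside each training fold and projects held-out
rows, removing even unsupervised leakage at the cost of noisier saliences
per fold. Both are provided because the two protocols answer slightly
different questions (replicating a published-style analysis vs. estimating
fully out-of-sample performance).

**Longitudinal hold-out.** Follow-up visits are standardized with baseline
statistics, projected on the baseline saliences, and predicted within the
same CV scheme such that a follow-up row is only ever predicted by models
whose training folds exclude that subject's baseline row; the exclusion is
asserted programmatically on every fold.

**Matched subsamples.** Severity matching is a threshold filter (e.g. a
CDR cut-off); age matching greedily pairs each member of the smallest
group with the unused nearest-age member of every other group within a
caliper (default 2 years), without replacement, and reports achieved
per-group means. Infeasible matching (disjoint age ranges) is an error
with diagnostics, not a silent partial match.

## Longitudinal change

Per subject, LV and block: rate = (follow-up score − baseline
score)/interval in years. Within-cohort change uses two-sided paired
t-tests on the raw differences; identical vectors return t = 0, p = 1
(flagged degenerate), while zero-variance nonzero differences leave p
undefined (flagged) because the statistic diverges. Rates are compared
between variants with pairwise two-sample t statistics under Tukey–Kramer
familywise correction: pooled within-group variance across all groups
(exact for unequal n under classical assumptions), p from the
studentized-range distribution with q = |t|·√2; Welch statistics are
available by flag for heteroscedastic rates. The paired-test family (LV ×
block) is reported both raw and BH-adjusted, since the appropriate
multiplicity convention for this family is not settled.

## The synthetic cohort generator

What it emulates: three patient groups (defaults 70/36/30) and a control
group (50), a 12-column cognition block named after a standard FTD
neuropsychology battery (names carry no semantics), a 102-region brain
block, age/sex/education with group-specific age distributions
(bvFTD ≈ 61.5 ± 6.4 y, svPPA ≈ 63 ± 6.3, nfvPPA ≈ 68.1 ± 7.9, controls
≈ 64 ± 7; education truncated normal ≥ 8 y), optional additive site
effects on the brain block, and follow-up visits at 1.03 ± 0.44 years for
a subset of patients (defaults 38/24/15) with group-specific yearly latent
drift, the semantic variant declining fastest on LV-1.

Generative model per patient and LV k: latent scores (t_x, t_y) are
bivariate normal with unit variances, correlation ρ_k (defaults 0.7, 0.5)
and a shared per-group mean shift; observed blocks are X = T_x U_trueᵀ +
demographic effects + residual noise and likewise for Y. Planted saliences
are unit-norm with disjoint random supports across LVs (sparsity 0.5 by
default), hence exactly orthonormal; non-zero loadings have equal
magnitude 1/√nnz with random signs. Controls carry demographic effects and
noise only.

Three identifiability-motivated design choices deserve explanation:

- **Variance-equalizing residuals.** Residual variance is heteroscedastic
  per column so that every column of a block has the same total variance.
  Since the analysis z-scores columns, unequal column variances would warp
  the planted saliences on the correlation scale (each loading divided by
  its own column SD), making "recover the planted salience" an ill-posed
  target. With equal variances, z-scoring is a uniform rescaling and the
  planted salience is exactly the population singular vector of R. The
  extra variance in weakly-loading columns reads naturally as
  pattern-unrelated individual variability.
- **Equal-magnitude loadings.** Random loading magnitudes would let a
  single dominant loading consume the variance budget of its block,
  degrading identifiability of the remaining entries; equal magnitudes
  spread the planted signal evenly.
- **Moment-fixed latents.** The latent scores of planted cohorts are drawn
  with their empirical mean/covariance fixed to the population values
  (whitening), so realized cross-block correlations equal ρ exactly at any
  n and estimated LVs are not rotated by sampling noise in the latent
  cross-moments. Null cohorts deliberately do *not* whiten: fixing
  cross-moments to zero would make the observed pairing atypically
  decoupled and bias permutation calibration; null latents are honest
  independent samples. A null cohort must be requested with ρ ≡ 0 and zero
  group shifts (shared group means would couple the blocks through the
  group structure); anything else is a validation error.

`noise_sd` (default 0.2) is the residual noise floor on the unit-latent
scale; the default was fixed at design time by a perturbation analysis of
the 12 × 102 cross-correlation problem (the planted singular value must
clear the random-matrix bulk edge ≈ (p_x p_y)^¼/√n at the study's n) so
that the generator's stated conditions are actually recoverable —
a cohort-scale analysis cannot detect an arbitrarily weak planted signal.
Group shifts (defaults separating the three variants by ~2–3 latent SD
pairwise) are what make the subtypes classifiable from LV scores.

What it does **not** emulate, hence what passing tests do not show about
real data: non-Gaussian marginals of real DBM values (skewed Jacobians,
ventricular expansion tails), heteroscedasticity across disease stages,
missing-not-at-random cognitive data, scanner/protocol differences beyond
an additive site offset, diagnostic label noise, and attrition that
correlates with severity. Recovery results on this generator demonstrate
correctness of the estimators under the stated model, not clinical
performance.

## Problem sizes used by tests and the acceptance script

Monte-Carlo sizes are the package's own choices, picked for clear
statistical margins at interactive runtimes: permutation calibration uses
200 null cohorts (n = 100) × 200 permutations; planted-structure recovery
50 seeds (n = 150) with 100 permutations / 200 bootstrap resamples per
seed; classifier calibration uses 3 × 50-subject blobs; the acceptance
script runs the full pipeline at the default cohort size with 500
permutations / 500 bootstraps and 10-fold × 100-repeat CV, plus scaled
calibration studies (100 null cohorts, 20 recovery seeds). Add-one
smoothing bounds the smallest achievable permutation p at 1/(n_perm + 1),
which the recovery criteria account for.

## Known limitations

- Sign-only bootstrap alignment (no Procrustes) inflates SEs for
  near-degenerate LV pairs.
- The default protocol's full-sample PLS is unsupervised leakage in the
  strict sense; use the nested mode for fully out-of-sample estimates.
- The greedy age-matching is not optimal matching; it can discard feasible
  solutions an optimal assignment would find.
- No mixed-effects longitudinal modelling: only the two-visit difference
  design, which ignores within-subject correlation structure beyond the
  paired difference.
- Site effects are carried as metadata and an optional additive offset;
  no harmonization is attempted.
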