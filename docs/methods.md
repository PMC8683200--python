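# Methods

`snvnet` implements a case–control association analysis for smoking-cessation
cohorts genotyped on a candidate-gene SNV panel: participants are
current/recent smokers or biochemically verified long-term ex-smokers, and
the question is which behavioral covariates and which of several hundred
candidate variants distinguish successful quitters. The pipeline has five
stages — univariate behavioral statistics, an SNV filtering cascade,
elastic-net penalized logistic regression, leave-one-out cross-validated AUC
model selection, and post-selection inference — plus a synthetic-cohort
generator that makes every stage testable without access to individual-level
data.

## Univariate statistics

Categorical exposures are summarized as 2×2 tables oriented so that OR > 1
means the exposure associates with current smoking (a/b = exposed/unexposed
smokers, c/d = the same for ex-smokers). The point odds ratio is the
cross-product `ad/bc` with **no continuity correction by default**: with the
published cell counts, the uncorrected ratio reproduces the printed point
estimates (e.g. a rare-exposure OR of 17.2 from a single exposed ex-smoker),
while a Haldane–Anscombe +0.5 would not. The correction is available behind
a flag. Confidence intervals are Woolf (log-OR) intervals,
`exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d))`. Zero cells yield an
infinite/undefined OR with an explicit flag, never a silent adjustment.

Test choice follows standard practice: Pearson chi-square (1 df, no Yates
correction) unless some expected cell count is below 5, in which case the
two-sided Fisher exact test (summing hypergeometric probabilities of tables
no more probable than the observed one). Continuous covariates use the
pooled-variance t-test when both groups have |skew| < 1 and the Mann–Whitney
U test (mid-ranks, normal approximation without continuity correction for
n > 20) otherwise. The race comparison is restricted to the two declared
categories (White vs Black), matching the reduced denominators of the
univariate table, and education is a 4×2 chi-square. Participants missing an
exposure are dropped from that exposure's table only, so denominators vary
by row.

## Filtering cascade

Stage order is fixed: **complete-case → variation → missingness → duplicate
collapse**. Complete-case restriction drops participants missing any
regression covariate (hazardous alcohol requires a present AUDIT score;
past-30-day marijuana; past-30-day cocaine; GAD-7 anxiety). The variation
filter removes SNVs whose *non-modal genotype fraction* among non-missing
calls is below 2% — "variation" is read as variability of the coded 0/1/2
value rather than minor-allele frequency, since a rare allele concentrated
in heterozygotes still carries regression information; both filters are
computed on the complete-case samples because duplicate detection is
explicitly scoped to those subjects and the two choices should be
consistent. The missingness filter removes SNVs with ≥ 5% missing calls.
Duplicate collapse groups SNVs with byte-identical genotype vectors
(missingness pattern included) over the complete-case samples and keeps the
lexicographically first id of each group — two SNVs that differ only on
excluded participants still collapse.

Retained SNVs enter the design as additive dosages; residual missing calls
(< 5% per column by construction) are imputed to the column's modal genotype,
which preserves the {0,1,2} support (mean imputation available behind a
flag). The outcome is coded 1 for ex-smokers by default, because the
multivariable model targets long-term nonsmoking status; the univariate
tables keep their smoker-exposure orientation through table layout, not by
recoding.

## Penalized logistic regression

The fitter minimizes the penalized average negative log-likelihood

    (1/n) Σ [log(1 + e^{η_i}) − y_i η_i] + λ Σ_j pf_j (α|β_j| + (1−α)β_j²/2)

by outer IRLS quadratic approximation and inner cyclic coordinate descent
with soft-thresholding (the glmnet scheme), written from first principles
with a numba-compiled kernel. Numerical choices:

* Columns are standardized internally to zero mean and unit (population)
  variance; λ lives on the standardized scale; coefficients are reported
  back-transformed. Zero-variance columns keep coefficient zero.
* The intercept is never penalized. All other predictors are penalized by
  default (`penalty_factors` of 1), including the four clinical covariates —
  the multivariable report lists them alongside SNVs as selected variables,
  consistent with penalizing everything; a flag exempts them.
* Convergence: max absolute standardized-coefficient change < `tol`
  (default 1e-7), with caps of 1000 outer IRLS iterations × 1000 inner
  sweeps. A step-halving safeguard keeps the penalized objective
  non-increasing across outer iterations. IRLS weights are floored at 1e-5
  with probabilities clipped at 1e-5 from the boundaries.
* The λ path is log-equally spaced over `n_lambda` points (default 100) from
  `λ_max = max_j |x̃_j'(y − ȳ)| / (n α)` down to `min_ratio·λ_max` (default
  0.01, the small-n/large-p convention). λ_max is inflated by a relative
  1e-9 so the top of the path sits strictly on the all-zero side of the KKT
  tie. For ridge (α = 0), whose λ_max is infinite, the anchor is computed at
  α = 0.001 so paths stay comparable across the mixing grid.
* Perfect separation at λ = 0 is reported as `converged=False`, never
  silently returned; `kkt_check` certifies any fit by its maximum
  subgradient violation.

## Leave-one-out CV and model selection

The grid is 3 mixing values α ∈ {0, 0.5, 1} × 100 penalties. For each fold,
column standardization is recomputed on the n−1 training samples (no
leakage) and the whole descending path is fit with warm starts; the n
held-out probabilities are pooled into one rank-based (Mann–Whitney) AUC per
grid point — per-fold AUC is undefined for single-sample folds, so pooling
is the only coherent leave-one-out reading. Ties at the best AUC break
toward larger λ, then larger α (sparser, then more lasso-like),
deterministically. Inside CV folds the coordinate-descent tolerance is 1e-5
with at most 50 outer IRLS iterations per grid point; non-converged fold
fits (quasi-separated fits at the smallest penalties) contribute their last
iterate.

One pooled-LOO property is worth knowing: the intercept-only model's pooled
LOO AUC is exactly **0**, not 0.5, because each held-out prediction is the
training-fold prevalence, which is lower exactly when the held-out sample is
a case. This is a known leave-one-out artifact, not a bug; truly constant
scores do give AUC 0.5.

## Post-selection inference

Selective p-values follow the polyhedral (truncated-Gaussian) framework with
a one-step Gaussian approximation for the logistic lasso at a fixed λ (λ is
treated as fixed; the CV step is not conditioned on, matching the sequential
description of the analysis). With active set M and sign vector s, the
one-step (debiased) estimator is `β̄ = β̂ + λ H⁻¹ s̃` where H is the average
information matrix at the lasso solution over the intercept-plus-active
columns and s̃ carries the active signs (zero for the intercept);
Σ = H⁻¹/n approximates its covariance. The event {sign(β̂_M) = s} is the
affine constraint `diag(s)(β̄_M − λ(H⁻¹s̃)_M) > 0`, which truncates each
coordinate of β̄ to an interval [V−, V+]; the p-value is the two-sided
truncated-Gaussian tail probability, computed with stable log-survival
differences, using the conservative rule `min(1, 2·min(p_right, p_left))`.
Under the global null, selective p-values of selected variables are uniform,
which is the testable form of false-discovery control at the nominal level —
the acceptance suite verifies this by simulation (KS test on pooled
p-values across 500 null cohorts).

Reported effect sizes are the one-step estimates — per-allele adjusted
log-odds for SNV columns, exponentiated to adjusted odds ratios — rather
than the shrunken lasso coefficients (`or_source="lasso"` exposes those).
No confidence intervals are emitted: there is no established construction
for intervals around these adjusted odds ratios. Two limits of the procedure
are deliberate: an empty active set returns an empty report with a warning,
and an ill-conditioned active-set information matrix (condition number
above 1e10) is an error naming the collinear columns. As λ → 0 the
truncation interval tends to (0, ∞), not (−∞, ∞): the coefficient's sign
remains conditioned on, so the limiting p-value is the sign-conditioned
Wald p (about twice the classical two-sided p for a clear effect). If the
CV optimum is not pure lasso, the report falls back to the best α = 1 grid
point, since the selection event is only characterized for the ℓ1 penalty.

## Synthetic cohorts

`generate_cohort` draws Hardy–Weinberg genotypes (two Bernoulli haplotypes
per sample) with Gaussian-copula linkage disequilibrium in blocks of 5
adjacent SNVs at latent correlation 0.7 — candidate-gene panels are heavily
autocorrelated — and plants designated degenerate columns: low-variation
SNVs (allele frequency 0.003, non-modal fraction < 2%), high-missingness
SNVs (missing rate 8% ≥ the 5% cut), and duplicate profiles copying a
partner column. Behavioral covariates are drawn with positive co-use
coupling (Gaussian copula, latent correlation 0.25) at realistic
prevalences (hazardous alcohol 0.15, marijuana 0.37, cocaine 0.19), and the
outcome follows a logistic model whose behavioral log-odds default to the
univariate association scale (ex-smoker orientation: −log 5.43 alcohol,
−log 3.73 marijuana, −log 17.2 cocaine, −0.08 per anxiety point) plus one
planted per-allele genetic effect of log 2.02; the intercept is calibrated
numerically so the mean simulated prevalence equals the target (0.268,
52/194). Defaults reproduce the study conditions: 194 participants
(142/52), 759 SNVs with 124/458/21 degenerate columns and 37 incomplete
phenotype records.

`study_mirror_fixture` is the deterministic counterpart: the filtering and
univariate accounting are *specification, not simulation*. For any seed it
yields exactly the published counts — 142/52 outcome split, the behavioral
2×2 margins cell-for-cell (61/139 vs 9/52 marijuana, 35/139 vs 1/52
cocaine, 25/131 vs 2/48 hazardous alcohol, 72/140 vs 24/52 male, 33/140 vs
12/52 Latino/a, 8-vs-0 White among declared race, the education
distribution), 37 participants missing a regression covariate (157 complete
cases), and a 759-column panel in which exactly 124 columns fail the
variation filter, 458 the missingness filter, and 21 duplicate another
column over the complete-case samples, leaving 156. The seed varies only
arbitrary filler (who exactly is exposed, the genotype draws); counts are
enforced by construction. What the fixture does **not** emulate: real LD
structure, Hardy–Weinberg departures, genotype–phenotype confounding, or
any true genetic effect — passing tests on it validates accounting and
machinery, not biological conclusions.

## Validation-simulation sizes

The heavier statistical checks in the test suite run at these sizes, chosen
to give stable verdicts at interactive runtimes on one CPU:

* label-permutation leakage guard: 50 replicates at n=157, p=156 over the
  full α grid with 20 λ per α and CV tolerance 1e-3 (these coarser settings
  reproduce the fine-grid best-AUC values on probe replicates);
* null-calibration of selective inference: 500 cohorts at n=157 with p=30
  independent SNVs, lasso at the 15th of 100 path points (≈ 0.5 λ_max, a
  sparse-selection regime appropriate to the one-step approximation);
* planted-effect recovery: 100 cohorts at n=157, p=156, one per-allele
  OR 2.0 effect, lasso at the 25th path point;
* strong-effect detection: 200 cohorts at n=500, p=10, per-allele
  log-OR 1.5.

## Known limitations

* The selective inference is asymptotic (one-step Gaussian approximation);
  at n ≈ 150 with dense active sets the approximation degrades — the report
  is computed at the CV-chosen penalty, which on real data may be deep in
  the path.
* Only biallelic SNVs are supported; multi-allelic VCF records are rejected
  rather than split.
* Gaussian/Poisson/multinomial families, k-fold CV variants, the
  one-standard-error rule, data carving and sample splitting are out of
  scope.
* The behavioral-only multivariable model is not a separate report surface;
  the unpenalized fitter (`newton_logistic`) is exposed for that purpose.
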