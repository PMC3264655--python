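# Methods

`recursig` reimplements, as a tested library, a microarray-era procedure for
discovering and validating a gene-expression signature of postoperative
recurrence from right-censored follow-up data. This note records the models,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## The pipeline

1. **Batch adjustment (DWD).** Expression from several institutions is merged
   after removing the systematic between-batch direction found by
   distance-weighted discrimination.
2. **Per-gene screening.** Each gene is tested in a Cox proportional-hazards
   model containing the gene and age, stratified by gender × stage, under B
   bootstrap resamples; genes are ranked by the fraction of resamples with
   Wald p < 0.01 and screened at frequency > 80%.
3. **Risk-score model (partial Cox regression).** A partial-least-squares
   analogue for censored outcomes builds K predictive components; composing
   component weights with component-level Cox coefficients gives one
   coefficient βᵢ per gene and the risk score
   scoreⱼ = Σᵢ βᵢ (xᵢⱼ − x̄ᵢ), with x̄ᵢ the per-gene training mean.
   Samples with score > 0 are called high-risk, score < 0 low-risk; an exact
   zero (measure-zero event) is assigned to low risk and logged.
4. **Signature selection.** Forward selection over the ranked list maximizes
   the training |Dxy| of the risk scores; leave-one-out cross-validation
   repeats the selection n times and keeps genes occurring in > 50% of folds.
5. **Evaluation.** Somers' Dxy / Harrell's C, time-dependent ROC/AUC under
   censoring, Kaplan–Meier curves and the Mantel–Haenszel log-rank test.
6. **Pathway scans.** The partial-Cox risk score restricted to each gene
   set's genes, dichotomized at zero, tested by log-rank.

## Survival core

Cox models are fitted by Newton–Raphson on the stratified partial likelihood
with Efron's tie correction (Breslow selectable). The engine is *batched*:
thousands of models sharing an outcome but differing in one covariate column
(one per gene) are fitted simultaneously with vectorized risk-set
accumulation; this is what makes a 200-resample bootstrap over 2,000 genes a
couple of minutes rather than hours. Convergence is declared when the
relative log-likelihood change falls below 1e-12 (single fits; 1e-9 in
batch); step-halving guards overshoot; models whose coefficients drift past
|β| = 15 are treated as monotone-likelihood (perfect separation) cases and
refitted with a small L2 penalty (1e-6·n), flagged. Steps that cannot
improve the likelihood within 12 halvings indicate a numerical optimum
(extreme coefficients underflowing the exponential); such models stop where
they are and are reported unconverged. Wald statistics give per-covariate
p-values; strata with zero events are dropped with a warning.

Proportional hazards are checked with scaled Schoenfeld residuals
(Grambsch–Therneau): residuals are correlated with a transform of event time
— Kaplan–Meier transform by default, identity and rank selectable — giving a
χ²₁ statistic per covariate. The implementation agrees with independent
implementations to ~6 decimals. At small n (~100) the KM transform is
mildly conservative (empirical size ~0.03 at nominal 0.05); the rank
transform is exactly calibrated there.

## Partial Cox regression

Component k's gene weights are proportional to the per-gene univariate Cox
coefficients fitted on the current residual matrix, with the linear
predictor of the previously extracted components entering as an offset;
weights are ℓ₂-normalized, and the residual matrix is deflated by ordinary
least-squares projection off the new component. K is chosen to maximize the
training |Dxy| (smallest K attaining the maximum; a trace over K = 1..K_max
is always recorded, K_max defaulting to 20). No variance scaling is applied
before component construction — the risk-score formula uses only centering —
but columns can be standardized upstream by the caller. No strata enter this
stage; stratification belongs to the screening model.

Training |Dxy| is non-decreasing in K up to small numerical noise, so
maximizing a *training* metric tends toward the largest feasible K and, in
forward selection, toward longer prefixes. This is inherent to the
procedure; the LOOCV occurrence-frequency filter is the overfitting control,
and the pure-noise specificity test shows it working (empty signatures on
data with no planted signal).

## Dxy sign convention

`ConcordanceResult.c_index` is Harrell's C in the risk direction: over
usable pairs (the earlier failure is an observed event, times distinct), the
probability that the sample failing earlier has the higher score; tied
scores count ½. `dxy` is the rank correlation of score with survival *time*:
Dxy = 2(C_time − 0.5) = −2(C − 0.5). A good risk score therefore has C near
1 and Dxy near −1, matching the convention in which strong training
signatures report Dxy ≈ −0.8.

## Time-dependent ROC

Cases at horizon t are subjects with an event by t, controls those surviving
beyond t. Both probabilities come from the bivariate law of (marker,
survival) estimated with a nearest-neighbor conditional Kaplan–Meier:
S(t | X = xᵢ) is the product-limit estimate over the samples whose marker
percentile lies within a symmetric span of xᵢ's (span default 0.25·n^(−1/5)).
Then sens(c,t) = [#{X>c} − Σ_{x>c}S(t|x)] / [n − ΣS(t|x)] and
spec(c,t) = 1 − Σ_{x>c}S(t|x) / ΣS(t|x), over the distinct observed cutoffs;
the curve is made monotone by cumulative max after sorting by false-positive
rate, and AUC(t) is the trapezoid area.

The smoothing exists solely to handle censoring. When no observation is
censored at or before t, the conditional survival is taken as the exact
indicator 1{Tᵢ > t} (the span → 0 limit): the estimator then reduces
*exactly* to the empirical Mann–Whitney two-sample AUC, and a noiseless
marker attains AUC(t) = 1 exactly. With smoothing left on, boundary blur
caps a perfect marker near 0.99 — an artifact of the bandwidth, not of the
marker — which is why the reduction is built in.

Single-number AUC summaries in this package are the mean of AUC(t) over a
stated grid (quartiles of observed event times by default). This is a
reporting convention of the package, stated wherever used.

## DWD batch adjustment

The DWD direction solves: minimize Σᵢ 1/rᵢ + C·Σᵢ ξᵢ over unit-norm w and
intercept b, with rᵢ = yᵢ(w·xᵢ + b) + ξᵢ > 0, ξᵢ ≥ 0. Eliminating the slacks
gives the equivalent smooth objective V(r) = 1/r for r ≥ 1/√C and
V(r) = 2√C − C·r below, minimized over the unit ball with a trust-region
constrained optimizer in the span of the data (SVD reduction, so the problem
dimension is at most the sample count). The penalty default is C = 100/d̄²
with d̄ the median cross-batch pairwise distance. Genes are standardized
before direction finding and the adjustment is mapped back to the original
scale. More than two batches merge successively, largest first (order
configurable); each merge translates both sides along w so projected means
meet the pooled mean. Survival columns pass through untouched.

The adjustment is a rank-1 translation per batch: it is exactly idempotent
on pure mean-shift data (within-batch variation in the span of the shift).
On generic noisy batches a second pass finds a fresh direction and removes a
further O(noise) mean component — repeated application contracts the
between-batch mean difference rather than fixing it in one step. No
direction-based method can do otherwise.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
chosen to resemble a four-institution stage I resection cohort:

| parameter | default | rationale |
|---|---|---|
| n_samples | 142 | training-cohort scale |
| n_genes | 2,000 | array-scale screening panel |
| n_signal | 20 | small planted prognostic set |
| beta_signal | 0.5 (alternating sign) | both protective and deleterious genes |
| baseline_hazard | 0.01 / month | median null recurrence time ≈ 69 months |
| censor_rate | 0.5 | roughly half recur over long follow-up |
| n_batches / batch_shift_sd | 4 / 0.5 | four institutions, additive shifts |
| signal_block_corr | 0.5 | co-expressed prognostic modules |
| age, gender, stage | N(65, 8), Bernoulli(½), IA/IB | cohort demographics |

Event times are exponential with hazard h₀·exp(Σ β_g x_g) (proportional
hazards hold exactly); censoring is an independent exponential whose rate is
solved by root bracketing so the expected censored fraction matches
`censor_rate`. Batch effects are additive per-(batch, gene) normal shifts on
the *measured* expression; the hazard uses the biological (pre-shift)
values, so the batch label is a technical artifact, not a confounder.
Covariates are simulated but do not enter the hazard, keeping the null
calibration of the adjusted screen clean.

Planted genes form two co-expressed modules — protective and deleterious —
sharing a latent factor with within-module correlation 0.5; marginally every
gene is standard normal. This mirrors how real prognostic genes behave
(signatures concentrate in adhesion / apoptosis / proliferation programs)
and it matters statistically: with fully independent planted genes, the
unexplained hazard variance from the other 19 genes attenuates each gene's
*marginal* association so strongly that no marginal screen — this one or any
other — would find it; module structure is what makes single-gene screening
of polygenic signals work in practice.

What the generator does **not** emulate: probe-level noise models,
intensity-dependent variance, cross-hybridization, non-proportional hazards,
informative censoring, or covariate-driven risk. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated generative assumptions, not performance on real cohort data.

## Cross-platform transfer

A validation platform is an independent cohort drawn from the same law —
identical planted gene identities and coefficients, fresh samples — whose
gene panel is missing ⌈dropout_frac · panel⌉ genes of a designated panel
(the planted genes, or a fitted signature). Transfer evaluation follows the
refit protocol: signature genes present on the test platform are
intersected, the partial Cox model is refit *on the test set*, and Dxy,
AUC(t) and the risk-group log-rank are computed there. A
coefficient-transfer mode is deliberately not the default.

Because the refit reuses the test outcomes both to fit the score and to
test the dichotomized groups, transfer log-rank p-values (and the pathway
scan's p-values, which share this structure) are optimistic: under permuted
outcomes the null rejection rate exceeds nominal by an amount that does not
vanish with n. They are reported as ranking/association evidence, not as
calibrated tests; the Dxy and AUC metrics do not suffer this double use in
the same way (under permutation they concentrate near their null values).

## LOOCV modes and problem sizes

`rerank_per_fold=True` recomputes the bootstrap ranking inside every fold —
no information from the withheld sample reaches the fold's selection, a
property verified by an outcome-poisoning test. The cheaper
`rerank_per_fold=False` reuses the global ranking across folds; it is the
mode used for the desk-scale recovery experiment (2,000 genes, 20 planted
at |β| = 0.8, n = 300, B = 200, components capped at K_max = 10 inside the
cross-validated selection), whose problem sizes were chosen so the whole
experiment — screen, 300-fold LOOCV, transfer with 37% signature-gene
dropout — runs in minutes on one core. Defaults elsewhere: B = 1,000 for
standalone ranking (Monte-Carlo error of a frequency ≤ ~0.016), B = 200
inside LOOCV, screening threshold 0.80 (strict), LOOCV frequency threshold
0.50 (strict), max_genes capped at 120.

## Pathway scan thresholds

The significance flag defaults to p < 1e-4; because published analyses of
this kind have used both 1e-4 and 1e-5, the threshold is a parameter and a
Bonferroni-adjusted column is emitted alongside the raw p-values. Genes
absent from the dataset are dropped from each set (counts reported);
duplicate members count once; sets with fewer than 2 genes present are
skipped and logged.

## Known limitations

- The signature-size choice maximizes a training metric; signatures lean
  large, and the LOOCV frequency filter, not the forward-selection stopping
  rule, is what controls noise admission.
- The bootstrap screen has a small but irreducible per-gene null admission
  rate: a gene with no association passes the 80% frequency bar when its
  full-data |z| exceeds roughly 2.58 + 0.84 ≈ 3.4, i.e. with probability
  ≈ 6×10⁻⁴ (measured 7.5×10⁻⁴ over 8,000 simulated null genes — the screen
  is exactly as calibrated as the normal approximation predicts). On a
  G-gene panel, expect ≈ G·6×10⁻⁴ stray genes per run; a stray screened
  gene then survives LOOCV (a one-gene ranked list is always selected), so
  "no signal in, empty signature out" holds only for panels of a few dozen
  genes. At array scale, a handful of false admissions among thousands of
  genes is the expected behavior, which is why recovery is judged by
  contamination *rate*, not emptiness.
- Log-rank p-values downstream of outcome-fitted dichotomization (transfer
  reports, pathway scans) are anti-conservative, as documented above.
- The Cox engine handles right censoring only: no delayed entry, no
  time-varying covariates, no competing risks.
- DWD removes additive batch shifts only; scale (variance) batch effects
  are out of contract.
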