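# Methods

This note documents the statistical machinery in `degeval`: the DE
calling conventions, the interpolated precision–recall analysis, the
benchmark predictors, the pseudobulk pipeline, what the synthetic
generators do and do not emulate, and the numerical and design choices
that were genuinely open.

## Notation and data model

An experiment is a pair (c, a) of a *context* c (cell type / cell line)
and an *action* a (perturbation), with a reserved control action (the
literal `"0"` by default; plate datasets use a negative-control compound
such as DMSO, configurable per run). Observed data are samples × genes
matrices with per-sample metadata; samples-in-rows is the canonical
internal orientation and readers transpose as needed. Matrices carry a
scale tag: `counts` (non-negative, summable) or `lognorm`
(log-normalized expression). Missing values are a hard error; gene-id
collisions are a hard error rather than silent deduplication, because
all downstream joins are by gene id. Train/test splits operate on
(context, action) pairs; control pairs are never held out.

## DEG calling

For a pair (c, a) against (c, 0):

- **Fold-change**: `lfc = log2((mean_a + ε) / (mean_0 + ε))` with
  pseudocount ε = 1e-6 (configurable). The pseudocount only matters for
  genes with near-zero means; `lfc(m, m) = 0` exactly for any m and ε.
- **Significance, cell level**: per-gene two-sample t-tests of perturbed
  vs control cells. Welch (unequal variances) is the default, a pooled
  variant exists; the pooled variant is algebraically identical to an
  intercept+action OLS, which the test suite asserts to 1e-9.
- **Significance, pseudobulk level**: per-gene OLS of log1p pseudobulk
  expression on an intercept, the target-action indicator and dummy-coded
  batch covariates; the reported statistic is the action coefficient's t
  with the residual degrees of freedom, and the coefficient (natural-log
  scale) is divided by ln 2 to report a log2 fold-change.
- **Label**: `Z_g = 1` iff `pvalue_g < p_thr` **and** `|lfc_g| > l_thr`,
  on *raw* p-values, defaults `p_thr = 1e-10`, `l_thr = 0.3`. The
  stringent p cutoff reflects well-powered single-cell group sizes
  (hundreds to thousands of cells); no multiple-testing correction is
  applied by default since the threshold operates far beyond any
  Bonferroni level at these powers. Labeling is monotone in both
  thresholds. The fold-change condition uses the absolute value, so
  strong down-regulation counts.
- p-values that underflow are floored at 1e-300 so −log10 p stays
  finite; zero-variance genes with equal means get (stat 0, p 1).

No empirical-Bayes variance moderation is applied: the linear model and
its covariates are specified directly and tested with ordinary t
statistics. Moderation mainly matters at very small replicate counts
and would tie results to a specific shrinkage implementation.

## Ranking scores and the interpolated PR curve

Predicted DE results are reduced to `R_g = |lfc_g| · 1[pvalue_g < p_thr]`.
Point-prediction models with no uncertainty get `R_g = |lfc_g|`
(indicator treated as 1). Signed scores were rejected because they would
rank strong down-regulation below weak up-regulation.

Thresholding R induces classifiers whose achievable operating points are
computed one per *distinct* score value — tied genes enter together,
because any within-tie ordering would be arbitrary and irreproducible.
The all-positive point (TP = P, FP = N) terminates every curve, so
recall 1 is always achievable at precision π; this also resolves the
degenerate constant-score ranking (a single operating point) cleanly.

Between consecutive achievable points A and B, TP interpolates linearly
and FP follows the local skew `s = (FP_B − FP_A)/(TP_B − TP_A)`:

    FP(t) = FP_A + s · (t − t_A),  precision(t) = t / (t + FP(t)).

The area over recall is computed in closed form per segment. With
`a = 1 + s` and `b = FP_A − s·t_A`:

    ∫ t/(a t + b) dt = (t_B − t_A)/a − (b/a²) · ln((t_B + FP_B)/(t_A + FP_A)),

summed over segments and divided by P. The initial segment from the
origin (0, 0) to the first operating point is included (its precision is
the constant `1/(1+s)`), which makes a perfect ranking score exactly 1
and a constant ranking score exactly π. Trapezoidal integration of
precision over the raw points was rejected: precision between achievable
points is hyperbolic, and linear interpolation overestimates the area.
The closed form is validated against an independent dense-grid numeric
integration (trapezoid on a TP grid aligned with the achievable points;
agreement ≲ 1e-9 on random small instances).

`precision_at_recall(curve, r)` evaluates the interpolation at
TP = r·P; at a corner shared by a vertical drop, the left (higher
precision) achievable value is used, and at r = 1 the terminal
all-positive precision π is returned by convention.

**Baseline.** `π = P/(P+N)` is reported with every evaluation. A
constant ranking attains it exactly (analytic identity, tested to
1e-12). A *random* ranking has expected precision π at every fixed rank
depth, but its expected interpolated AUC-PR is slightly **above** π:
the area integrates precision over recall, and recall increments arrive
exactly where positives do, correlating the integrand with the measure.
Exact enumeration at P = 1, N = 2 gives a mean of 0.4986 vs π = 1/3;
at P = 30, N = 6968 the excess is ≈ 12% of π. The often-quoted
statement that random rankings average to π is therefore an
idealization, and one calibration test asserting it within Monte-Carlo
error fails by design — it documents the true behaviour rather than
weakening the check.

**R²** is everywhere the squared Pearson correlation (not 1 − SSE/SST),
reported over all genes, over the DEG subset, and between fold-change
vectors. Degenerate cases (zero variance, e.g. the identically-zero
fold-changes of a control-mean predictor) are reported as not
applicable rather than as a number.

## Benchmark predictors

- **Cell-type model**: predicts the control mean of the target context
  for any action. By construction its fold-changes are zero, its rank
  scores are identically zero, and its AUC-PR equals π on any labeling —
  an exact identity, asserted as such. It is the negative control that
  exposes what R² misses.
- **Perturbation model**: predicts the context-ignoring mean of all
  training samples sharing the action. The precise prediction rule is
  this package's construction for a single-factor action-only regression
  (the natural counterpart of the cell-type model).
- **Two-factor model**: per-gene additive `α_gc + β_ga` on the log
  scale, control as the reference level for actions (β_g0 = 0). Fitting
  is closed-form OLS on one shared design factorization reused across
  genes — contractually identical to independent per-gene regressions.
  Counts data is log1p-transformed for fitting and predictions are
  back-transformed with expm1 (clipped at 0); log-normalized data is
  fitted as-is. Per-gene residual variances and the residual df feed the
  t test of β_ga = 0; β̂ divided by ln 2 is the reported fold-change.
  With all β̂ forced to zero the predictions coincide with the cell-type
  model's (nesting identity). β̂ recovery follows the expected n^(−1/2)
  root-mean-square-error scaling.

External models enter via adapters: `sampled_prediction_de` for
distribution predictors (fold-change of the sample mean vs the in vitro
control mean; per-gene t-tests of predicted samples against control
cells — the number of predicted cells defaults to whatever the caller
provides; matching the in vitro perturbed-group size is the sensible
choice), and `point_prediction_de` for mean-only predictors (no
p-values; ranking falls back to |lfc|).

## Pseudobulk pipeline

`pseudobulk_sum` sums raw counts within (context, action, donor, plate,
row) groups; per-gene totals are conserved exactly. Sums of
log-normalized values are refused. `filter_complete_pairs` keeps only
(context, action) pairs observed in the required number of donors
(default 3, the full-design value); it is idempotent and applies the
same rule to control pairs.

`population_de` fits log1p pseudobulk expression on the action indicator
plus donor, plate-within-donor and row dummies. Plate labels are recoded
within donor because plates are nested in donors (a plate determines its
donor), which would otherwise alias the dummies; the recode spans the
same column space at full rank. The *in silico* branch maps a per-donor
predicted count vector onto the perturbation groups at the same plate
locations as the ground truth, keeps the in vitro control groups, and
runs the identical model — so feeding the in vitro counts through the
prediction branch reproduces the in vitro result bitwise (asserted).
Predictions made on a log scale are returned to counts with expm1 and
optional per-group size factors; size factors default to the observed
totals of the matched in vitro groups, since the back-transform is
otherwise under-determined.

## Synthetic data

The generators exist so every claim above is testable without external
downloads. They emulate design structure and statistical regime, not the
marginal distributions of any real dataset.

**Single-cell generator** (`pbmc_like_config`): C = 7 contexts ×
(control + 1 stimulation), 6998 genes, 200 cells per pair, 30 true DEGs
— the shape of a multi-cell-type interferon-stimulation experiment.
Gene baselines are uniform on [1, 4] (log-normalized units) with
Gaussian context deviations (SD 0.4) floored at 0.05; cell noise is
Gaussian on the same scale (SD 0.6) clipped at zero, normalized
expression being non-negative. Effects are sparse: up-regulation
(probability 0.75) adds Uniform[1.0, 2.5]; down-regulation removes a
uniform 50–90% fraction of the smallest context baseline, so every group
mean stays positive while the fold-change clears the 0.3 threshold
comfortably. Context/baseline variance dominates effect variance — the
regime in which a control-mean predictor achieves R² ≥ 0.95 while
carrying zero DE signal, which is the dissociation the framework is
built to expose. Effect sizes are specified on the generator's
log-normalized scale; because the pipeline's fold-change is the log2
ratio of mean log-normalized values, a "log2-unit" effect has no exact
additive counterpart, and the generator's truth labels are the β
support, not re-derived from the realized fold-changes. A
negative-binomial mode (dispersion 10) produces counts for pipelines
that need them.

**Plate generator** (`plate_like_config`): 3 donors × 2 plates × 8 rows,
every plate's first three columns occupied by control compounds
(negative control first — giving each control action 16 locations per
donor), one randomly assigned well per perturbation per donor, all cell
types in every well. Defaults are desk-scaled: 800 genes, 12
perturbations on 6-column plates, 6 cell types, 20 cells per type per
well (a full 12-column, 144-perturbation, 18k-gene layout is a config
change, not a code change). Counts are negative-binomial around
`exp(baseline + context + action + donor + plate + row)` with additive
log-scale batch effects (SD 0.1) — deliberately within the span of the
DE model's covariates so the pipeline can remove them exactly.

**Null pseudobulk generator** (`simulate_null_pseudobulk`): emits
group-level log1p profiles directly (Gaussian noise, additive batch
effects keyed the way the model codes them, zero action effect) so that
the OLS t p-values are *exactly* t-distributed under the null. This
isolates the calibration of the DE model itself from the separate
question of how well log1p of NB sums approximates normality; type-I
error at 0.05 and KS-uniformity are asserted on this generator.

`corrupt_predictions` adds Gaussian noise (clipped at zero) to the true
pair means, giving a model-free dial from oracle predictions to noise
for degradation studies.

What the generators do **not** emulate: zero inflation and
gene–gene correlation of real scRNA-seq, library-size variation between
wells, donor-by-action interactions, and realistic fold-change spectra.
Passing tests therefore demonstrate the correctness and calibration of
the evaluation machinery under its stated assumptions, not predictive
performance on real data.

## Determinism and reporting

All generators consume a single seeded `numpy` Generator; the same seed
reproduces datasets bit for bit. CLI runs write a manifest (package
version, seed, configuration hash, input checksums) and serialize JSON
numbers at 6 significant digits so reruns diff byte-identically. Exit
codes: 0 success, 2 usage error, 1 computation error.

## Known limitations

- The evaluation needs at least one ground-truth DEG per pair; pairs
  with none are rejected rather than scored (π and the PR curve are
  undefined).
- `linear_model_de` is ordinary least squares: no voom-style precision
  weights, no shrinkage. At 3 perturbation replicates per pair its
  stringent-threshold calls are conservative.
- The count-scale back-transform for log-scale predictions is
  under-determined without library-size information; the size-factor
  convention above is a documented stand-in.
- Per-pair evaluation treats genes as exchangeable; no gene-set or
  correlation structure enters the PR analysis.
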