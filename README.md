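# degeval

**Evaluating in silico cellular-perturbation models by their ability to
identify differentially expressed genes.**

In silico perturbation models predict how gene expression responds to a
perturbation (a drug, a gene knockout, a stimulation) in a cellular
context (a cell type or cell line) that was never measured. The standard
way to score such models — R², the squared Pearson correlation between
predicted and observed expression across genes — rewards getting
baselines and housekeeping genes right, which any model that memorizes
the unperturbed state can do. It says almost nothing about the question
practitioners actually care about: *did the model find the genes the
perturbation changed?*

`degeval` scores models as DEG classifiers instead. It is aimed at
computational biologists benchmarking perturbation-response predictors
(autoencoder samplers, foundation models, or plain linear baselines) on
single-cell or pseudo-bulked expression data.

## The evaluation in brief

For a perturbed pair (c, a) vs its control (c, 0):

1. **Ground truth.** Call in vitro DEGs with the indicator
   `Z_g = 1[p_g < p_thr and |l_g| > l_thr]`, where `l_g` is the log2
   fold-change of group means and `p_g` a two-sample t (cell level) or a
   covariate-adjusted linear-model p-value (pseudobulk level). Defaults:
   `p_thr = 1e-10`, `l_thr = 0.3`.
2. **Ranking scores.** From the model's predicted DE result, score every
   gene `R_g = |l̂_g| · 1[p̂_g < p_thr]` (point predictors without
   p-values fall back to `|l̂_g|`). Thresholding `R_g` traces a family of
   classifiers from stringent to permissive.
3. **Interpolated PR curve.** Each distinct score gives an achievable
   operating point (TP, FP); between points, TP interpolates linearly and
   FP follows the local skew, so precision `t / (t + FP(t))` traces a
   hyperbolic path. The area (AUC-PR) is integrated in closed form per
   segment — trapezoids on raw PR points would overestimate it. The
   **baseline AUC-PR** is the DEG prevalence `π = P / (P + N)`; a
   constant ranking achieves exactly π, so π is the minimum useful score.

The package also reports the conventional R² suite (all genes, DEGs
only, and on the fold-change scale) so the dissociation between the two
views is visible pair by pair.

## Worked example

Simulate a 4-cell-type dataset with known ground truth (2000 genes, 30
true DEGs per stimulation, log-normalized scale), call DEGs, and
benchmark the built-in predictors with leave-pair-out fitting:

```bash
degeval simulate --kind single-cell --out demo --seed 7 \
    --n-genes 2000 --n-contexts 4 --cells-per-pair 100 --deg-fraction 0.015
degeval de --data demo/dataset.tsv --metadata demo/dataset.meta.tsv --out demo/de
degeval benchmark --data demo/dataset.tsv --metadata demo/dataset.meta.tsv \
    --seed 7 --out demo/bench
```

The DE step reports 30 DEGs per pair (baseline π = 0.015); the benchmark
prints, per held-out pair and model:

```
context action        model   r2_all   r2_deg   r2_lfc   auc_pr  baseline  precision_at_0.25  precision_at_0.5  precision_at_0.75
    ct0   stim    cell-type 0.942127 0.425353      NaN 0.015000     0.015           0.015000          0.015000           0.015000
    ct0   stim perturbation 0.777781 0.889388 0.131393 0.241824     0.015           0.333333          0.312500           0.113350
    ct0   stim   two-factor 0.989823 0.997452 0.652241 1.000000     0.015           1.000000          1.000000           1.000000
```

Read the first row carefully — it is the point of the package. The
**cell-type model** predicts the control mean for every perturbation, so
its R² over all genes is excellent (0.94) while its fold-changes are
identically zero: its AUC-PR equals the 0.015 baseline *exactly*, and
its fold-change R² is undefined (reported as NaN). The **two-factor
model** (additive cell type + condition effects on the log scale,
extrapolating the condition effect from the other cell types) has a
similar R² but separates the 30 true DEGs perfectly. R² cannot tell
these two models apart in any way that matters; AUC-PR can.

The same machinery handles plate-structured designs: `--kind plate`
simulates 3 donors × 2 plates × 8 rows with control columns and
negative-binomial counts; `pseudobulk_sum`, `filter_complete_pairs` and
`population_de` aggregate counts per (cell type, action, donor, plate,
row), keep donor-complete pairs, and test the action coefficient in a
per-gene OLS with donor / plate-within-donor / row covariates — applied
identically to in vitro counts and to model predictions mapped back to
the count scale at the same plate locations.

## Library surface

```python
import degeval as dg

ds, truth = dg.simulate_single_cell(dg.pbmc_like_config(), seed=1)
invitro   = dg.invitro_de(ds, "ct0", "stim")            # ground-truth labels
params    = dg.fit_two_factor_model(ds, train_pairs)    # benchmark predictor
pred_de   = dg.two_factor_de(params, "stim")            # predicted DE
report    = dg.evaluate_pair(invitro, pred_de)          # AUC-PR, baseline, P@R, R²
```

External models plug in through `PredictionSet` (per-pair mean vectors,
TSV) scored via `point_prediction_de`, or — for distribution-predicting
models — through `sampled_prediction_de(samples, control_cells)`.

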