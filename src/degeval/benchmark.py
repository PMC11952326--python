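"""End-to-end benchmarking: ground-truth DE → predictions → evaluation.

The cell-level workflow mirrors the leave-one-pair-out protocol: for each
held-out (context, action) pair the benchmark predictors are fitted on
the remaining pairs, their DE results are derived, and the pair is scored
with the PR/R² suite against in vitro DEG labels. The population-level
workflow does the same on pseudobulk data, fitting per donor and pushing
predictions through the identical covariate-adjusted DE pipeline as the
in vitro branch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import ObservedPairSet, PerturbationDataset
from .de_core import DEResult, DEThresholds, group_mean, label_degs, log2_fold_change, two_sample_t
from .metrics import EvaluationReport, evaluate_pair
from .predictors import (
    fit_cell_type_model,
    fit_perturbation_model,
    fit_two_factor_model,
    point_prediction_de,
    predict_two_factor,
    two_factor_de,
)
from .pseudobulk import PseudobulkDataset, population_de, to_count_scale

__all__ = [
    "invitro_de",
    "benchmark_cell_level",
    "benchmark_population",
    "report_table",
]

MODELS = ("cell-type", "perturbation", "two-factor")


def invitro_de(
    dataset: PerturbationDataset,
    context: str,
    action: str,
    *,
    thresholds: DEThresholds = DEThresholds(),
    variant: str = "welch",
    pseudocount: float = 1e-6,
) -> DEResult:
    """Ground-truth DE for one pair: group means, t-test vs control, labels."""
    a_cells = dataset.matrix[dataset.mask(context, action)]
    c_cells = dataset.matrix[dataset.mask(context, dataset.control_action)]
    if a_cells.shape[0] < 2 or c_cells.shape[0] < 2:
        raise ValueError(f"pair ({context!r}, {action!r}) needs >= 2 cells per condition")
    lfc = log2_fold_change(a_cells.mean(axis=0), c_cells.mean(axis=0), pseudocount)
    stat, pval = two_sample_t(a_cells, c_cells, variant=variant)
    de = DEResult(gene_ids=dataset.gene_ids, lfc=lfc, stat=stat, pvalue=pval)
    de.label = label_degs(de, thresholds)
    return de


def _predict_pair(model_name, dataset, train, context, action, thresholds, pseudocount):
    """(pred_mean, pred_de) for one model on one held-out pair."""
    control_mean = group_mean(dataset, context, dataset.control_action)
    if model_name == "cell-type":
        model = fit_cell_type_model(dataset, train)
        pred_mean = model.predict(context, action)
        pred_de = point_prediction_de(
            pred_mean, control_mean, gene_ids=dataset.gene_ids, pseudocount=pseudocount
        )
    elif model_name == "perturbation":
        model = fit_perturbation_model(dataset, train)
        pred_mean = model.predict(context, action)
        pred_de = point_prediction_de(
            pred_mean, control_mean, gene_ids=dataset.gene_ids, pseudocount=pseudocount
        )
    elif model_name == "two-factor":
        params = fit_two_factor_model(dataset, train)
        pred_mean = predict_two_factor(params, context, action)
        pred_de = two_factor_de(params, action, thresholds)
    else:
        raise ValueError(f"unknown model {model_name!r}")
    return pred_mean, pred_de


def benchmark_cell_level(
    dataset: PerturbationDataset,
    test_pairs=None,
    *,
    models=MODELS,
    thresholds: DEThresholds = DEThresholds(),
    recalls=(0.25, 0.5, 0.75),
    pseudocount: float = 1e-6,
) -> dict:
    """Leave-pair-out benchmark of the linear predictors on cell-level data.

    For every test pair, each model is fitted on all observed pairs except
    that pair, and its DE prediction is scored against the in vitro DEG
    labels. Returns ``{(context, action): {model: EvaluationReport}}``.
    """
    if test_pairs is None:
        test_pairs = sorted(dataset.perturbation_pairs())
    results: dict = {}
    for context, action in test_pairs:
        truth = invitro_de(dataset, context, action, thresholds=thresholds, pseudocount=pseudocount)
        if truth.label.sum() == 0:
            raise ValueError(
                f"pair ({context!r}, {action!r}) has no in vitro DEGs at the given thresholds"
            )
        obs_mean = group_mean(dataset, context, action)
        train = ObservedPairSet(
            pairs=frozenset(dataset.pairs() - {(context, action)}), role="train"
        )
        per_model = {}
        for name in models:
            pred_mean, pred_de = _predict_pair(
                name, dataset, train, context, action, thresholds, pseudocount
            )
            per_model[name] = evaluate_pair(
                truth,
                pred_de,
                recalls,
                thresholds=thresholds,
                obs_mean=obs_mean,
                pred_mean=pred_mean,
            )
        results[(context, action)] = per_model
    return results


def report_table(results: dict) -> pd.DataFrame:
    """Flatten a benchmark result dict into a tidy comparison table."""
    rows = []
    for (context, action), per_model in sorted(results.items()):
        for model, rep in per_model.items():
            row = {
                "context": context,
                "action": action,
                "model": model,
                "r2_all": rep.r2_all,
                "r2_deg": rep.r2_deg,
                "r2_lfc": rep.r2_lfc,
                "auc_pr": rep.auc_pr,
                "baseline": rep.baseline,
            }
            for r, v in rep.precision_at.items():
                row[f"precision_at_{r}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Population-level (pseudobulk) benchmark


def benchmark_population(
    pb: PseudobulkDataset,
    test_pairs,
    *,
    models=MODELS,
    thresholds: DEThresholds = DEThresholds(),
    recalls=(0.25, 0.5, 0.75),
) -> dict:
    """Benchmark the linear predictors on a pseudobulk plate design.

    Per donor, each model is fitted on the log1p pseudobulk profiles of
    all pairs except the test pairs; predictions are back-transformed to
    the count scale and pushed through the same covariate-adjusted DE
    pipeline (donor, plate-within-donor, row) as the in vitro branch.
    Per-donor R² values (log scale, all genes) are attached to each
    report. Returns ``{(context, action): {model: EvaluationReport}}``.
    """
    test_pairs = [(str(c), str(a)) for c, a in test_pairs]
    ds = pb.to_dataset()
    donors = sorted(pb.meta["donor"].unique())
    excluded = set(test_pairs)
    results: dict = {}
    for context, action in test_pairs:
        truth = population_de(pb, context, action, thresholds=thresholds)
        if truth.label.sum() == 0:
            raise ValueError(
                f"pair ({context!r}, {action!r}) has no in vitro DEGs at the given thresholds"
            )
        per_model = {}
        for name in models:
            predicted_counts = {}
            r2_by_donor = {}
            for donor in donors:
                d_mask = (ds.obs["donor"] == donor).to_numpy()
                d_ds = ds.subset(d_mask)
                train = ObservedPairSet(
                    pairs=frozenset(d_ds.pairs() - excluded), role="train"
                )
                if name == "two-factor":
                    params = fit_two_factor_model(d_ds, train)
                    pred_counts = predict_two_factor(params, context, action)
                else:
                    # single-factor models fitted on the log1p scale, then
                    # back-transformed — same convention as the two-factor fit
                    sub = d_ds.subset(
                        np.fromiter(
                            (
                                (c, a) in train.pairs
                                for c, a in zip(d_ds.obs["context"], d_ds.obs["action"])
                            ),
                            dtype=bool,
                            count=d_ds.n_samples,
                        )
                    )
                    if name == "cell-type":
                        m = sub.mask(context, pb.control_action)
                        if not m.any():
                            raise ValueError(f"no control groups for context {context!r}, donor {donor!r}")
                    else:
                        m = sub.mask(action=action)
                        if not m.any():
                            raise ValueError(f"action {action!r} unseen in training for donor {donor!r}")
                    pred_counts = to_count_scale(np.log1p(sub.matrix[m]).mean(axis=0))
                predicted_counts[donor] = pred_counts
                obs_mask = d_ds.mask(context, action)
                if obs_mask.any():
                    obs_log = np.log1p(d_ds.matrix[obs_mask].mean(axis=0))
                    try:
                        from .metrics import r_squared

                        r2_by_donor[donor] = r_squared(np.log1p(pred_counts), obs_log)
                    except ValueError:
                        r2_by_donor[donor] = None
            pred_de = population_de(
                pb, context, action, predicted_counts=predicted_counts, thresholds=thresholds
            )
            rep = evaluate_pair(truth, pred_de, recalls, thresholds=thresholds)
            rep.r2_all = (
                float(np.mean([v for v in r2_by_donor.values() if v is not None]))
                if any(v is not None for v in r2_by_donor.values())
                else None
            )
            rep.precision_at = dict(rep.precision_at)
            per_model[name] = rep
        results[(context, action)] = per_model
    return results
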