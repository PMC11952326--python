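"""Linear benchmark predictors and DE adapters for external models.

Three reference predictors span the difficulty scale of out-of-sample
perturbation prediction:

* **cell-type model** — predicts the control mean of the target context
  for every action. It assumes expression is unchanged by perturbation,
  so its fold-changes are identically zero and its AUC-PR equals the DEG
  prevalence π on any labeling: a useful negative control exposing what
  R² alone cannot.
* **perturbation model** — predicts the context-ignoring mean of all
  training samples sharing the action.
* **two-factor model** — per-gene additive model on the log scale,
  log x_gca = α_gc + β_ga with β_g0 = 0 for control. The action
  coefficient doubles as the DE effect: testing β_ga = 0 yields p-values,
  and β̂_ga (in log2 units) is the predicted fold-change, so the model
  supports the full ranking-score evaluation.

Distribution-predicting external models (e.g. variational autoencoders
that sample post-perturbation cells) enter through
:func:`sampled_prediction_de`; point-prediction models through
:func:`point_prediction_de` (fold-changes only, no p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from .data_model import ObservedPairSet, PerturbationDataset
from .de_core import (
    LN2,
    DEResult,
    DEThresholds,
    _floor_p,
    group_mean,
    label_degs,
    log2_fold_change,
    two_sample_t,
)

__all__ = [
    "CellTypeModel",
    "PerturbationModel",
    "TwoFactorParams",
    "fit_cell_type_model",
    "fit_perturbation_model",
    "fit_two_factor_model",
    "predict_two_factor",
    "two_factor_de",
    "sampled_prediction_de",
    "point_prediction_de",
]


def _train_mask(dataset: PerturbationDataset, train: ObservedPairSet | None) -> np.ndarray:
    if train is None:
        return np.ones(dataset.n_samples, dtype=bool)
    keys = list(zip(dataset.obs["context"], dataset.obs["action"]))
    allowed = train.pairs
    return np.fromiter((k in allowed for k in keys), dtype=bool, count=len(keys))


@dataclass
class CellTypeModel:
    """Control-mean predictor: x̂_ca = control mean of context c."""

    control_means: dict  # context -> gene vector (native scale)
    gene_ids: np.ndarray

    def predict(self, context: str, action: str | None = None) -> np.ndarray:
        if context not in self.control_means:
            raise ValueError(f"unknown context {context!r}")
        return self.control_means[context].copy()


def fit_cell_type_model(
    dataset: PerturbationDataset, train: ObservedPairSet | None = None
) -> CellTypeModel:
    mask = _train_mask(dataset, train)
    sub = dataset.subset(mask)
    means = {}
    for c in dataset.contexts:
        m = sub.mask(c, dataset.control_action)
        if not m.any():
            raise ValueError(f"context {c!r} has no control samples in the training set")
        means[c] = sub.matrix[m].mean(axis=0)
    return CellTypeModel(control_means=means, gene_ids=dataset.gene_ids)


@dataclass
class PerturbationModel:
    """Action-mean predictor: the grand mean over all training samples of an action."""

    action_means: dict  # action -> gene vector (native scale)
    gene_ids: np.ndarray

    def predict(self, context: str | None, action: str) -> np.ndarray:
        if action not in self.action_means:
            raise ValueError(f"action {action!r} was not observed in training")
        return self.action_means[action].copy()


def fit_perturbation_model(
    dataset: PerturbationDataset, train: ObservedPairSet | None = None
) -> PerturbationModel:
    mask = _train_mask(dataset, train)
    sub = dataset.subset(mask)
    means = {}
    for a in dataset.actions:
        m = sub.mask(action=a)
        if m.any():
            means[a] = sub.matrix[m].mean(axis=0)
    if not means:
        raise ValueError("no actions observed in the training set")
    return PerturbationModel(action_means=means, gene_ids=dataset.gene_ids)


# ----------------------------------------------------------------------
# Two-factor model


@dataclass
class TwoFactorParams:
    """Fitted per-gene additive context + action model on the log scale."""

    contexts: list
    actions: list  # perturbation actions (control excluded from the design)
    control_action: str
    alpha: np.ndarray  # (n_contexts, n_genes)
    beta: np.ndarray  # (n_actions + control row of zeros handled via lookup)
    resid_var: np.ndarray  # per-gene residual variance
    df_resid: int
    xtx_inv_diag: np.ndarray  # per-design-column (X'X)^-1 diagonal
    gene_ids: np.ndarray
    scale: str  # native scale of the training data ("counts" or "lognorm")

    def beta_for(self, action: str) -> np.ndarray:
        if action == self.control_action:
            return np.zeros(self.alpha.shape[1])
        try:
            j = self.actions.index(action)
        except ValueError:
            raise ValueError(f"action {action!r} not in fitted model") from None
        return self.beta[j]

    def alpha_for(self, context: str) -> np.ndarray:
        try:
            i = self.contexts.index(context)
        except ValueError:
            raise ValueError(f"context {context!r} not in fitted model") from None
        return self.alpha[i]


def _to_log(matrix: np.ndarray, scale: str) -> np.ndarray:
    return np.log1p(matrix) if scale == "counts" else matrix


def _from_log(values: np.ndarray, scale: str) -> np.ndarray:
    return np.maximum(np.expm1(values), 0.0) if scale == "counts" else values


def fit_two_factor_model(
    dataset: PerturbationDataset, train: ObservedPairSet | None = None
) -> TwoFactorParams:
    """Per-gene closed-form OLS of log expression on context + action dummies.

    One shared design factorization is reused across all genes; results are
    identical to independent per-gene regressions. Counts-scale data is
    log1p-transformed first; log-normalized data is fitted as-is. Residual
    variances and degrees of freedom are stored for the β = 0 test.
    """
    mask = _train_mask(dataset, train)
    sub = dataset.subset(mask)
    contexts = sorted(sub.obs["context"].unique())
    actions = sorted(a for a in sub.obs["action"].unique() if a != dataset.control_action)
    n = sub.n_samples
    cols, names = [], []
    for c in contexts:
        cols.append((sub.obs["context"] == c).to_numpy(dtype=float))
        names.append(f"context[{c}]")
    for a in actions:
        cols.append((sub.obs["action"] == a).to_numpy(dtype=float))
        names.append(f"action[{a}]")
    X = np.column_stack(cols)
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        # name an aliased context/action pair for the error message
        raise ValueError(
            "rank-deficient two-factor design: some action is confounded with a "
            f"context on the observed training pairs (columns: {names})"
        )
    df_resid = n - k
    if df_resid < 1:
        raise ValueError(f"zero residual degrees of freedom (n={n}, k={k})")
    Y = _to_log(sub.matrix, dataset.scale)
    q, r = np.linalg.qr(X)
    coef = scipy.linalg.solve_triangular(r, q.T @ Y)
    resid = Y - X @ coef
    resid_var = (resid**2).sum(axis=0) / df_resid
    rinv = scipy.linalg.solve_triangular(r, np.eye(k))
    xtx_inv_diag = (rinv**2).sum(axis=1)
    return TwoFactorParams(
        contexts=contexts,
        actions=actions,
        control_action=dataset.control_action,
        alpha=coef[: len(contexts)],
        beta=coef[len(contexts):],
        resid_var=resid_var,
        df_resid=df_resid,
        xtx_inv_diag=xtx_inv_diag,
        gene_ids=dataset.gene_ids,
        scale=dataset.scale,
    )


def predict_two_factor(params: TwoFactorParams, context: str, action: str) -> np.ndarray:
    """Native-scale prediction α̂_c + β̂_a (back-transformed for counts data)."""
    log_pred = params.alpha_for(context) + params.beta_for(action)
    return _from_log(log_pred, params.scale)


def two_factor_de(
    params: TwoFactorParams,
    action: str,
    thresholds: DEThresholds = DEThresholds(),
) -> DEResult:
    """Per-gene t test of the action effect β_ga = 0.

    The fold-change is β̂_ga converted to log2 units (the fitting scale is
    a natural-log scale); the statistic uses the stored residual variance
    with the model's residual degrees of freedom. Labels follow the
    standard DEG indicator.
    """
    if params.df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    if action == params.control_action:
        raise ValueError("control action has no DE effect to test")
    j = params.actions.index(action) if action in params.actions else None
    if j is None:
        raise ValueError(f"action {action!r} not in fitted model")
    beta = params.beta[j]
    var_scale = params.xtx_inv_diag[len(params.contexts) + j]
    se = np.sqrt(np.maximum(params.resid_var * var_scale, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta / se
    stat[~np.isfinite(stat) & (np.abs(beta) < 1e-12)] = 0.0
    pval = 2.0 * scipy.stats.t.sf(np.abs(stat), params.df_resid)
    bad = ~np.isfinite(stat)
    pval[bad] = 0.0
    stat[bad] = np.sign(beta[bad]) * np.inf
    de = DEResult(gene_ids=params.gene_ids, lfc=beta / LN2, stat=stat, pvalue=_floor_p(pval))
    de.label = label_degs(de, thresholds)
    return de


# ----------------------------------------------------------------------
# Adapters for external model predictions


def sampled_prediction_de(
    samples: np.ndarray,
    control_cells: np.ndarray,
    thresholds: DEThresholds = DEThresholds(),
    *,
    gene_ids: np.ndarray | None = None,
    pseudocount: float = 1e-6,
    variant: str = "welch",
) -> DEResult:
    """DE from a distribution-predicting model's sampled cells.

    Fold-change is log2(mean(samples) / control mean) with a pseudocount;
    significance comes from per-gene two-sample t-tests of the predicted
    samples against the in vitro control cells.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    control_cells = np.atleast_2d(np.asarray(control_cells, dtype=float))
    if samples.shape[0] < 2 or control_cells.shape[0] < 2:
        raise ValueError(
            f"need >= 2 predicted samples and >= 2 control cells, got "
            f"{samples.shape[0]} and {control_cells.shape[0]}"
        )
    lfc = log2_fold_change(samples.mean(axis=0), control_cells.mean(axis=0), pseudocount)
    stat, pval = two_sample_t(samples, control_cells, variant=variant)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(samples.shape[1])], dtype=object)
    de = DEResult(gene_ids=gene_ids, lfc=lfc, stat=stat, pvalue=pval)
    de.label = label_degs(de, thresholds)
    return de


def point_prediction_de(
    pred_mean: np.ndarray,
    control_mean: np.ndarray,
    *,
    gene_ids: np.ndarray | None = None,
    pseudocount: float = 1e-6,
) -> DEResult:
    """Fold-change-only DE for point predictions without uncertainty.

    No p-values are produced; downstream ranking treats the significance
    indicator as 1 and scores genes by |lfc| alone.
    """
    lfc = log2_fold_change(pred_mean, control_mean, pseudocount)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(len(lfc))], dtype=object)
    return DEResult(gene_ids=gene_ids, lfc=lfc, stat=None, pvalue=None)
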