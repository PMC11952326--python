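"""Differential-expression statistics and DEG labeling.

A gene is called differentially expressed (DE) for a perturbed pair
(c, a) versus its control (c, 0) when it passes *both* a raw p-value
cutoff and an absolute log2 fold-change cutoff:

    Z_g = 1  iff  pvalue_g < p_thr  and  |lfc_g| > l_thr.

Defaults (p_thr = 1e-10, l_thr = 0.3) correspond to stringent DE calling
on well-powered single-cell comparisons. Fold-changes are log2 ratios of
group means with a small pseudocount; significance comes from two-sample
t-tests (Welch by default) or, for batch-structured pseudo-bulk designs,
from per-gene ordinary-least-squares fits with covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

__all__ = [
    "DEThresholds",
    "DEResult",
    "group_mean",
    "log2_fold_change",
    "two_sample_t",
    "linear_model_de",
    "label_degs",
]

#: numerical floor applied to p-values so -log10(p) stays finite
P_FLOOR = 1e-300

LN2 = np.log(2.0)


@dataclass(frozen=True)
class DEThresholds:
    """DEG-calling cutoffs: raw p-value and absolute log2 fold-change."""

    p_thr: float = 1e-10
    l_thr: float = 0.3

    def __post_init__(self):
        if not (0.0 < self.p_thr < 1.0):
            raise ValueError(f"p_thr must lie in (0, 1), got {self.p_thr}")
        if self.l_thr < 0:
            raise ValueError(f"l_thr must be >= 0, got {self.l_thr}")


@dataclass
class DEResult:
    """Per-gene DE statistics: log2 fold-change, test statistic, p-value.

    ``pvalue`` may be ``None`` for point-prediction models that provide no
    uncertainty (fold-changes only); downstream ranking then falls back to
    |lfc| alone.
    """

    gene_ids: np.ndarray
    lfc: np.ndarray
    stat: np.ndarray | None = None
    pvalue: np.ndarray | None = None
    label: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.lfc = np.asarray(self.lfc, dtype=float)
        n = len(self.gene_ids)
        if self.lfc.shape != (n,):
            raise ValueError("lfc length differs from gene_ids")
        if self.stat is not None:
            self.stat = np.asarray(self.stat, dtype=float)
            if self.stat.shape != (n,):
                raise ValueError("stat length differs from gene_ids")
        if self.pvalue is not None:
            self.pvalue = np.asarray(self.pvalue, dtype=float)
            if self.pvalue.shape != (n,):
                raise ValueError("pvalue length differs from gene_ids")
            if ((self.pvalue <= 0) | (self.pvalue > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=int)
            if self.label.shape != (n,):
                raise ValueError("label length differs from gene_ids")
            if not np.isin(self.label, (0, 1)).all():
                raise ValueError("labels must be binary")

    @property
    def neg_log10_p(self) -> np.ndarray | None:
        if self.pvalue is None:
            return None
        return -np.log10(self.pvalue)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids.astype(str), "lfc": self.lfc})
        df["stat"] = self.stat if self.stat is not None else np.nan
        df["pvalue"] = self.pvalue if self.pvalue is not None else np.nan
        df["neg_log10_p"] = -np.log10(df["pvalue"])
        df["label"] = self.label if self.label is not None else -1
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DEResult":
        df = pd.read_csv(path, sep="\t")
        label = df["label"].to_numpy()
        return cls(
            gene_ids=df["gene_id"].to_numpy(dtype=object),
            lfc=df["lfc"].to_numpy(),
            stat=None if df["stat"].isna().all() else df["stat"].to_numpy(),
            pvalue=None if df["pvalue"].isna().all() else df["pvalue"].to_numpy(),
            label=None if (label < 0).all() else label,
        )


# ----------------------------------------------------------------------


def group_mean(dataset, context: str, action: str) -> np.ndarray:
    """Arithmetic mean expression over the samples of one (context, action)."""
    m = dataset.mask(context, action)
    if not m.any():
        raise ValueError(f"no samples for pair ({context!r}, {action!r})")
    return dataset.matrix[m].mean(axis=0)


def log2_fold_change(mean_a: np.ndarray, mean_0: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """log2((mean_a + eps) / (mean_0 + eps)), elementwise.

    Means must be non-negative (expression); the pseudocount guards genes
    with zero mean in either group.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_0 = np.asarray(mean_0, dtype=float)
    if mean_a.shape != mean_0.shape:
        raise ValueError("mean vectors differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (mean_a < 0).any() or (mean_0 < 0).any():
        raise ValueError("negative group mean: expression must be non-negative")
    return np.log2((mean_a + pseudocount) / (mean_0 + pseudocount))


def _floor_p(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_FLOOR, 1.0)


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, variant: str = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene two-sample t-test between two samples × genes matrices.

    Returns (stat, pvalue); the statistic is positive when ``group_a`` has
    the larger mean. Genes with zero variance in both groups and equal
    means get stat 0, p = 1; zero variance with unequal means yields an
    infinite statistic and the p-value floor.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"each group needs >= 2 samples, got {a.shape[0]} and {b.shape[0]}"
        )
    if variant not in ("welch", "pooled"):
        raise ValueError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
    stat = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=0) - b.mean(axis=0)
    degenerate = ~np.isfinite(stat)
    same = degenerate & (np.abs(diff) < 1e-12)
    stat[same] = 0.0
    pval[same] = 1.0
    apart = degenerate & ~same
    stat[apart] = np.sign(diff[apart]) * np.inf
    pval[apart] = P_FLOOR
    return stat, _floor_p(pval)


def label_degs(de: DEResult, thr: DEThresholds = DEThresholds()) -> np.ndarray:
    """Binary DE indicator: pvalue < p_thr AND |lfc| > l_thr."""
    if de.pvalue is None:
        raise ValueError("labeling requires p-values")
    return ((de.pvalue < thr.p_thr) & (np.abs(de.lfc) > thr.l_thr)).astype(int)


# ----------------------------------------------------------------------
# Design-matrix linear model DE (pseudo-bulk pipeline)


def _build_design(meta: pd.DataFrame, target_action: str, control_action: str,
                  covariates: Sequence[str]) -> tuple[np.ndarray, list[str], int]:
    """Intercept + action indicator + dummy-coded covariates.

    Returns (X, column names, index of the target-action column).
    """
    actions = set(meta["action"])
    if target_action not in actions:
        raise ValueError(f"target action {target_action!r} absent from design metadata")
    if control_action not in actions:
        raise ValueError(f"control action {control_action!r} absent from design metadata")
    extra = actions - {target_action, control_action}
    if extra:
        raise ValueError(f"design metadata contains unexpected actions: {sorted(extra)}")
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    cols.append((meta["action"] == target_action).to_numpy(dtype=float))
    names.append(f"action[{target_action}]")
    for cov in covariates:
        levels = sorted(meta[cov].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((meta[cov].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    return X, names, 1


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on earlier ones (QR with pivoting)."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def linear_model_de(
    matrix: np.ndarray,
    meta: pd.DataFrame,
    target_action: str,
    *,
    control_action: str = "0",
    covariates: Sequence[str] | None = None,
    gene_ids: np.ndarray | None = None,
    log_base: str = "e",
    thresholds: DEThresholds | None = None,
) -> DEResult:
    """Covariate-adjusted per-gene OLS differential expression.

    Fits, for every gene, log-scale expression on an intercept, a
    target-action indicator (vs the control level) and dummy-coded batch
    covariates (e.g. donor, plate, row). The reported statistic is the t
    statistic of the action coefficient with the residual degrees of
    freedom; the fold-change is that coefficient converted to log2 units
    (``log_base="e"`` divides by ln 2; ``"2"`` reports it unchanged).

    The rows of ``matrix`` must align with ``meta`` and contain only the
    target and control actions.
    """
    Y = np.atleast_2d(np.asarray(matrix, dtype=float))
    if Y.shape[0] != len(meta):
        raise ValueError(f"matrix/metadata dimension mismatch: {Y.shape[0]} vs {len(meta)}")
    if covariates is None:
        covariates = [c for c in ("donor", "plate", "row") if c in meta.columns and meta[c].nunique() > 1]
    X, names, j_target = _build_design(meta, str(target_action), str(control_action), covariates)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError(f"rank-deficient design: aliased columns {_aliased_columns(X, names)}")
    df_resid = n - k
    if df_resid < 1:
        raise ValueError(f"zero residual degrees of freedom (n={n}, k={k})")

    q, r = np.linalg.qr(X)
    coef = scipy.linalg.solve_triangular(r, q.T @ Y)
    resid = Y - X @ coef
    sigma2 = (resid**2).sum(axis=0) / df_resid
    rinv = scipy.linalg.solve_triangular(r, np.eye(k))
    xtx_inv_diag = (rinv**2).sum(axis=1)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_diag[j_target], 0.0))
    beta = coef[j_target]
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta / se
    degenerate = ~np.isfinite(stat)
    stat[degenerate & (np.abs(beta) < 1e-12)] = 0.0
    pval = 2.0 * scipy.stats.t.sf(np.abs(stat), df_resid)
    pval[~np.isfinite(stat)] = P_FLOOR
    stat[~np.isfinite(stat)] = np.sign(beta[~np.isfinite(stat)]) * np.inf
    pval = _floor_p(pval)
    lfc = beta / LN2 if log_base == "e" else beta.copy()
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(Y.shape[1])], dtype=object)
    de = DEResult(gene_ids=gene_ids, lfc=lfc, stat=stat, pvalue=pval)
    if thresholds is not None:
        de.label = label_degs(de, thresholds)
    return de
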