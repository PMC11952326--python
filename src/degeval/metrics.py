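"""Ranking scores, interpolated precision–recall curves, AUC-PR and R².

A model's DE prediction for a pair (c, a) is reduced to a per-gene
ranking score

    R_g = |lfc_g| * 1(pvalue_g < p_thr)

and thresholding R_g traces a family of DEG classifiers from stringent to
permissive. Each distinct score value yields one achievable operating
point (TP, FP); tied scores enter together. Between achievable points the
true-positive count interpolates linearly while false positives follow
the local skew

    FP(t) = FP_A + s * (t - t_A),   s = (FP_B - FP_A) / (TP_B - TP_A),

so precision t / (t + FP(t)) follows a hyperbolic — not linear — path.
The area under the curve is integrated segment-by-segment in closed form:
with a = 1 + s and b = FP_A - s * t_A,

    ∫ t / (a t + b) dt = (t_B - t_A) / a - (b / a²) * ln((t_B + FP_B) / (t_A + FP_A)),

divided by P to express the area over recall. Linear (trapezoidal)
interpolation of precision would systematically overestimate this area.

The baseline AUC-PR equals the DEG prevalence π = P / (P + N): both a
constant-score classifier and a random ranking achieve it, so π is the
minimum useful performance under class imbalance.

R² throughout is the *squared Pearson correlation* between predicted and
observed vectors (not the coefficient of determination 1 - SSE/SST).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_core import DEResult, DEThresholds

__all__ = [
    "PRCurve",
    "rank_scores",
    "pr_curve",
    "auc_pr",
    "baseline_auc_pr",
    "precision_at_recall",
    "r_squared",
    "lfc_r_squared",
    "EvaluationReport",
    "evaluate_pair",
]


@dataclass
class PRCurve:
    """Achievable operating points of the DEG-classifier family.

    ``thresholds``, ``tp`` and ``fp`` are aligned arrays in descending
    score order; the last point is always the all-positive classifier
    (TP = P, FP = N), so recall 1 is always achievable with precision π.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    P: int
    N: int

    @property
    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(denom > 0, self.tp / np.maximum(denom, 1), 1.0)
        return prec

    @property
    def recall(self) -> np.ndarray:
        return self.tp / self.P

    @property
    def baseline(self) -> float:
        return self.P / (self.P + self.N)

    @property
    def auc(self) -> float:
        return auc_pr(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "precision": self.precision,
                "recall": self.recall,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_scores(de: DEResult, p_thr: float = 1e-10, no_pvalue_mode: bool | None = None) -> np.ndarray:
    """Per-gene ranking score |lfc| * 1(pvalue < p_thr).

    Point-prediction models without p-values (``de.pvalue is None`` or
    ``no_pvalue_mode=True``) are scored by |lfc| alone, treating the
    significance indicator as 1.
    """
    if no_pvalue_mode is None:
        no_pvalue_mode = de.pvalue is None
    mag = np.abs(de.lfc)
    if no_pvalue_mode:
        return mag
    if de.pvalue is None:
        raise ValueError("DEResult has no p-values; use no_pvalue_mode")
    return mag * (de.pvalue < p_thr)


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """Operating points of the classifier family induced by the scores.

    One point per distinct score value (all tied genes enter together),
    in descending order; the terminal all-positive point is part of every
    curve. Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores/labels length mismatch: {scores.shape} vs {labels.shape}")
    labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    P = int(labels.sum())
    N = int(labels.size - P)
    if P == 0:
        raise ValueError("no positive labels: PR analysis is undefined without DEGs")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # indices of the last element of each tie group
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    last = np.append(boundary, scores.size - 1)
    tp = np.cumsum(l_sorted)[last]
    fp = (last + 1) - tp
    return PRCurve(thresholds=s_sorted[last], tp=tp, fp=fp, P=P, N=N)


def _segments(curve: PRCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Consecutive (t_A, f_A, t_B, f_B) including the initial (0,0) anchor."""
    t = np.concatenate(([0.0], curve.tp.astype(float)))
    f = np.concatenate(([0.0], curve.fp.astype(float)))
    return t[:-1], f[:-1], t[1:], f[1:]


def auc_pr(curve: PRCurve) -> float:
    """Exact area under the skew-interpolated PR curve.

    Each segment contributes its closed-form logarithmic antiderivative;
    vertical segments (no TP gain) contribute nothing. The initial segment
    from the origin to the first operating point is included, so a perfect
    ranking scores exactly 1 and a constant ranking scores exactly π.
    """
    ta, fa, tb, fb = _segments(curve)
    dt = tb - ta
    live = dt > 0
    ta, fa, tb, fb, dt = ta[live], fa[live], tb[live], fb[live], dt[live]
    s = (fb - fa) / dt
    a = 1.0 + s
    b = fa - s * ta
    area = dt / a
    denom = ta + fa
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log((tb + fb) / denom)
    nz = b != 0.0
    area[nz] -= (b[nz] / a[nz] ** 2) * log_term[nz]
    return float(area.sum() / curve.P)


def baseline_auc_pr(labels: np.ndarray) -> float:
    """DEG prevalence π = positives / total genes."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return float(labels.astype(float).mean())


def precision_at_recall(curve: PRCurve, r: float) -> float:
    """Precision of the interpolated curve at recall exactly ``r`` in (0, 1]."""
    if not (0.0 < r <= 1.0):
        raise ValueError(f"recall must lie in (0, 1], got {r}")
    if r == 1.0:
        # the curve terminates at the all-positive point, precision π
        return curve.baseline
    t_star = r * curve.P
    ta, fa, tb, fb = _segments(curve)
    for i in range(len(ta)):
        if tb[i] - ta[i] <= 0:
            continue
        if ta[i] <= t_star <= tb[i]:
            s = (fb[i] - fa[i]) / (tb[i] - ta[i])
            f_star = fa[i] + s * (t_star - ta[i])
            return float(t_star / (t_star + f_star))
    # t_star == 0 cannot happen (r > 0); falling through means r > 1 epsilon-wise
    raise RuntimeError("recall target outside the achievable curve")


def r_squared(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Squared Pearson correlation between prediction and observation."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred/obs length mismatch")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        pred, obs = pred[mask], obs[mask]
    if pred.size < 3:
        raise ValueError(f"need >= 3 entries for a correlation, got {pred.size}")
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def lfc_r_squared(pred_lfc: np.ndarray, obs_lfc: np.ndarray) -> float:
    """R² on the log fold-change scale (squared Pearson correlation)."""
    return r_squared(pred_lfc, obs_lfc)


# ----------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-pair evaluation bundle: R² suite + PR summary."""

    auc_pr: float
    baseline: float
    precision_at: dict
    r2_all: float | None = None
    r2_deg: float | None = None
    r2_lfc: float | None = None
    curve: PRCurve | None = None

    def to_dict(self) -> dict:
        return {
            "r2_all": self.r2_all,
            "r2_deg": self.r2_deg,
            "r2_lfc": self.r2_lfc,
            "auc_pr": self.auc_pr,
            "baseline": self.baseline,
            "precision_at": dict(self.precision_at),
        }

    def to_json(self, path=None, ndigits: int = 6) -> str:
        def _round(v):
            if isinstance(v, dict):
                return {k: _round(x) for k, x in v.items()}
            if isinstance(v, float):
                return float(f"{v:.{ndigits}g}")
            return v

        text = json.dumps(_round(self.to_dict()), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _align(truth: DEResult, pred: DEResult) -> DEResult:
    t_ids = pd.Index(truth.gene_ids.astype(str))
    p_ids = pd.Index(pred.gene_ids.astype(str))
    if t_ids.equals(p_ids):
        return pred
    diff = set(t_ids).symmetric_difference(set(p_ids))
    if diff:
        raise ValueError(f"gene universes differ; symmetric difference: {sorted(diff)[:10]}"
                         f"{' ...' if len(diff) > 10 else ''}")
    pos = p_ids.get_indexer(t_ids)
    return DEResult(
        gene_ids=truth.gene_ids,
        lfc=pred.lfc[pos],
        stat=None if pred.stat is None else pred.stat[pos],
        pvalue=None if pred.pvalue is None else pred.pvalue[pos],
        label=None if pred.label is None else pred.label[pos],
    )


def evaluate_pair(
    truth: DEResult,
    pred: DEResult,
    recalls=(0.25, 0.5, 0.75),
    *,
    thresholds: DEThresholds = DEThresholds(),
    obs_mean: np.ndarray | None = None,
    pred_mean: np.ndarray | None = None,
    keep_curve: bool = False,
) -> EvaluationReport:
    """Score one test pair: ranking → PR curve → AUC-PR + the R² suite.

    ``truth`` must carry DE labels (ground-truth Z); ``pred`` provides the
    fold-changes and (optionally) p-values from which rank scores are
    computed. Gene universes must match as sets; predictions are aligned
    to the truth's gene order by id. When mean-expression vectors are
    supplied, R² over all genes and over the DEG subset is reported; a
    degenerate R² (zero variance, e.g. identically-zero predicted
    fold-changes) is reported as ``None`` (not applicable).
    """
    if truth.label is None:
        raise ValueError("truth DEResult must carry DE labels")
    pred = _align(truth, pred)
    scores = rank_scores(pred, p_thr=thresholds.p_thr)
    curve = pr_curve(scores, truth.label)
    auc = auc_pr(curve)
    prec_at = {r: precision_at_recall(curve, r) for r in recalls}

    def _safe_r2(x, y, mask=None):
        if x is None or y is None:
            return None
        try:
            return r_squared(x, y, mask)
        except ValueError:
            return None

    return EvaluationReport(
        auc_pr=auc,
        baseline=curve.baseline,
        precision_at=prec_at,
        r2_all=_safe_r2(pred_mean, obs_mean),
        r2_deg=_safe_r2(pred_mean, obs_mean, truth.label.astype(bool)),
        r2_lfc=_safe_r2(pred.lfc, truth.lfc),
        curve=curve if keep_curve else None,
    )
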