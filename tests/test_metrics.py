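import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import degeval as dg
from degeval.de_core import DEResult


def numeric_auc(curve, n_grid=100_000):
    """Independent oracle: dense-grid integration of interpolated precision.

    Evaluates the skew interpolation FP(t) = FP_A + s (t - t_A) on a TP
    grid aligned with the achievable points (so no grid cell straddles a
    kink) and integrates precision over recall by trapezoid.
    """
    tp = np.concatenate(([0.0], curve.tp.astype(float)))
    fp = np.concatenate(([0.0], curve.fp.astype(float)))
    live = [
        (tp[i], fp[i], tp[i + 1], fp[i + 1])
        for i in range(len(tp) - 1)
        if tp[i + 1] > tp[i]
    ]
    per_seg = max(2, n_grid // max(1, len(live)))
    total = 0.0
    for ta, fa, tb, fb in live:
        ts = np.linspace(ta, tb, per_seg)
        s = (fb - fa) / (tb - ta)
        fs = fa + s * (ts - ta)
        denom = ts + fs
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(denom > 0, ts / np.maximum(denom, 1e-300), 0.0)
        if denom[0] == 0.0:  # segment leaving the origin: constant precision limit
            prec[0] = 1.0 / (1.0 + s)
        total += np.trapezoid(prec, ts)
    return float(total / curve.P)


def random_instance(rng, max_genes=12):
    n = int(rng.integers(3, max_genes + 1))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n))] = 1
    rng.shuffle(labels)
    scores = rng.choice([0.0, 0.3, 0.7, 1.2, 2.5], size=n)  # deliberate ties
    return scores, labels


# ----------------------------------------------------------------------
# rank scores


def _de(lfc, pvalue):
    return DEResult(
        gene_ids=np.array([f"g{i}" for i in range(len(lfc))], dtype=object),
        lfc=np.asarray(lfc, dtype=float),
        pvalue=None if pvalue is None else np.asarray(pvalue, dtype=float),
    )


@pytest.mark.parametrize(
    "lfc,p,expected",
    [(0.8, 1e-12, 0.8), (0.8, 1e-3, 0.0), (-0.6, 1e-12, 0.6)],
)
def test_rank_score_is_absolute_lfc_gated_on_significance(lfc, p, expected):
    assert dg.rank_scores(_de([lfc], [p]), p_thr=1e-10)[0] == pytest.approx(expected)


def test_rank_score_without_pvalues_falls_back_to_magnitude():
    assert dg.rank_scores(_de([-0.9], None))[0] == pytest.approx(0.9)


# ----------------------------------------------------------------------
# PR curve construction


def test_pr_curve_known_points_and_closed_form_area():
    curve = dg.pr_curve(np.array([4.0, 3.0, 2.0, 1.0]), np.array([1, 0, 1, 0]))
    np.testing.assert_array_equal(curve.tp, [1, 1, 2, 2])
    np.testing.assert_array_equal(curve.fp, [0, 1, 1, 2])
    expected = 0.5 + 0.5 * (1 - np.log(1.5))
    assert dg.auc_pr(curve) == pytest.approx(expected, abs=1e-12)


def test_constant_scores_single_segment_at_prevalence():
    curve = dg.pr_curve(np.full(4, 1.0), np.array([1, 0, 1, 0]))
    assert len(curve.tp) == 1
    assert dg.auc_pr(curve) == pytest.approx(0.5, abs=1e-15)
    for r in (0.25, 0.5, 0.75, 1.0):
        assert dg.precision_at_recall(curve, r) == pytest.approx(0.5, abs=1e-15)


def test_perfect_ranking_scores_exactly_one():
    curve = dg.pr_curve(np.array([4.0, 3.0, 2.0, 1.0]), np.array([1, 1, 0, 0]))
    assert dg.auc_pr(curve) == pytest.approx(1.0, abs=1e-15)
    for r in (0.25, 0.5, 0.75):
        assert dg.precision_at_recall(curve, r) == pytest.approx(1.0)


def test_pr_curve_requires_a_positive_label():
    with pytest.raises(ValueError, match="no positive"):
        dg.pr_curve(np.arange(4.0), np.zeros(4, dtype=int))


def test_tied_scores_enter_as_one_operating_point():
    curve = dg.pr_curve(np.array([2.0, 2.0, 1.0]), np.array([1, 0, 1]))
    np.testing.assert_array_equal(curve.tp, [1, 2])
    np.testing.assert_array_equal(curve.fp, [1, 1])


def test_curve_ends_at_the_all_positive_point():
    rng = np.random.default_rng(0)
    for _ in range(20):
        scores, labels = random_instance(rng)
        curve = dg.pr_curve(scores, labels)
        assert curve.tp[-1] == curve.P and curve.fp[-1] == curve.N
        assert (np.diff(curve.tp) >= 0).all()
        assert dg.precision_at_recall(curve, 1.0) == pytest.approx(curve.baseline)


def test_closed_form_auc_matches_dense_grid_oracle():
    rng = np.random.default_rng(123)
    worst = 0.0
    for _ in range(60):
        scores, labels = random_instance(rng)
        curve = dg.pr_curve(scores, labels)
        worst = max(worst, abs(dg.auc_pr(curve) - numeric_auc(curve)))
    assert worst < 1e-6


@given(
    P=st.integers(1, 40),
    N=st.integers(0, 400),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_constant_classifier_auc_is_prevalence_for_any_imbalance(P, N):
    labels = np.concatenate([np.ones(P, dtype=int), np.zeros(N, dtype=int)])
    curve = dg.pr_curve(np.zeros(P + N), labels)
    assert dg.auc_pr(curve) == pytest.approx(P / (P + N), abs=1e-12)


def test_promoting_a_positive_above_all_negatives_never_hurts():
    rng = np.random.default_rng(7)
    for _ in range(30):
        scores, labels = random_instance(rng)
        base = dg.auc_pr(dg.pr_curve(scores, labels))
        extended_scores = np.append(scores, scores.max() + 1.0)
        extended_labels = np.append(labels, 1)
        refined = dg.auc_pr(dg.pr_curve(extended_scores, extended_labels))
        assert refined >= base - 1e-12


def test_baseline_prevalence_examples():
    assert round(dg.baseline_auc_pr(np.r_[np.ones(30), np.zeros(6968)]), 3) == 0.004
    assert round(dg.baseline_auc_pr(np.r_[np.ones(101), np.zeros(6897)]), 3) == 0.014
    assert dg.baseline_auc_pr(np.zeros(10)) == 0.0


def test_precision_at_recall_on_interpolated_segment():
    curve = dg.pr_curve(np.array([4.0, 3.0, 2.0, 1.0]), np.array([1, 0, 1, 0]))
    # r = 0.75 -> TP = 1.5 on the segment (1,1) -> (2,1): FP stays 1
    assert dg.precision_at_recall(curve, 0.75) == pytest.approx(1.5 / 2.5)


def test_precision_at_recall_rejects_out_of_range():
    curve = dg.pr_curve(np.array([1.0, 0.0]), np.array([1, 0]))
    for r in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            dg.precision_at_recall(curve, r)


# ----------------------------------------------------------------------
# R²


def test_r_squared_identity_and_affine_invariance():
    obs = np.array([1.0, 2.0, 4.0, 8.0])
    assert dg.r_squared(obs, obs) == pytest.approx(1.0)
    assert dg.r_squared(2 * obs + 5, obs) == pytest.approx(1.0)


def test_r_squared_hand_computed_example():
    assert dg.r_squared(np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])) == pytest.approx(0.25)


def test_r_squared_zero_variance_is_undefined():
    with pytest.raises(ValueError, match="variance"):
        dg.r_squared(np.ones(5), np.arange(5.0))


def test_lfc_r_squared_identity():
    v = np.array([0.1, -0.5, 1.2, 0.0])
    assert dg.lfc_r_squared(v, v) == pytest.approx(1.0)


# ----------------------------------------------------------------------
# evaluate_pair


def _truth_and_pred(n=50, seed=0):
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i}" for i in range(n)], dtype=object)
    label = np.zeros(n, dtype=int)
    label[:5] = 1
    lfc = np.where(label, rng.uniform(1, 2, n), rng.normal(0, 0.05, n))
    truth = DEResult(gene_ids=genes, lfc=lfc, pvalue=np.full(n, 1e-12), label=label)
    pred = DEResult(gene_ids=genes, lfc=lfc.copy(), pvalue=np.full(n, 1e-12))
    return truth, pred


def test_oracle_predictions_score_near_one():
    truth, pred = _truth_and_pred()
    rep = dg.evaluate_pair(truth, pred)
    assert rep.auc_pr > 0.99
    assert rep.baseline == pytest.approx(0.1)


def test_report_is_invariant_to_prediction_gene_order():
    truth, pred = _truth_and_pred()
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(pred.gene_ids))
    shuffled = DEResult(
        gene_ids=pred.gene_ids[perm], lfc=pred.lfc[perm], pvalue=pred.pvalue[perm]
    )
    r1 = dg.evaluate_pair(truth, pred)
    r2 = dg.evaluate_pair(truth, shuffled)
    assert r1.auc_pr == pytest.approx(r2.auc_pr, abs=1e-15)
    assert r1.precision_at == r2.precision_at


def test_gene_universe_mismatch_lists_difference():
    truth, pred = _truth_and_pred()
    bad = DEResult(
        gene_ids=np.append(pred.gene_ids[:-1], "novel"), lfc=pred.lfc, pvalue=pred.pvalue
    )
    with pytest.raises(ValueError, match="novel"):
        dg.evaluate_pair(truth, bad)


def test_zero_fold_change_predictions_hit_the_baseline_exactly():
    truth, pred = _truth_and_pred()
    flat = DEResult(gene_ids=pred.gene_ids, lfc=np.zeros_like(pred.lfc), pvalue=pred.pvalue)
    rep = dg.evaluate_pair(truth, flat)
    assert rep.auc_pr == pytest.approx(rep.baseline, abs=1e-15)
    assert rep.r2_lfc is None  # degenerate correlation reported as not applicable


def test_report_serializes_documented_keys(tmp_path):
    truth, pred = _truth_and_pred()
    rep = dg.evaluate_pair(truth, pred)
    import json

    text = rep.to_json(tmp_path / "r.json")
    data = json.loads(text)
    assert set(data) == {"r2_all", "r2_deg", "r2_lfc", "auc_pr", "baseline", "precision_at"}
    assert set(map(float, data["precision_at"])) == {0.25, 0.5, 0.75}
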