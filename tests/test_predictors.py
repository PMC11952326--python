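import numpy as np
import pandas as pd
import pytest
import scipy.stats

import degeval as dg
from degeval.de_core import DEThresholds


def _dataset(rows, matrix, scale="lognorm", control="0"):
    obs = pd.DataFrame(rows, columns=["context", "action"])
    return dg.PerturbationDataset(
        matrix=np.asarray(matrix, dtype=float),
        gene_ids=np.array([f"g{i}" for i in range(np.asarray(matrix).shape[1])], dtype=object),
        obs=obs,
        scale=scale,
        control_action=control,
    )


# ----------------------------------------------------------------------
# cell-type model


def test_cell_type_model_predicts_the_control_mean():
    ds = _dataset(
        [("c", "0"), ("c", "0"), ("c", "stim")],
        [[1.0, 2.0], [3.0, 4.0], [9.0, 9.0]],
    )
    model = dg.fit_cell_type_model(ds)
    np.testing.assert_allclose(model.predict("c", "stim"), [2.0, 3.0])


def test_cell_type_model_fold_changes_are_identically_zero():
    ds = _dataset(
        [("c", "0"), ("c", "0"), ("c", "stim"), ("c", "stim")],
        np.random.default_rng(0).uniform(1, 5, size=(4, 10)),
    )
    model = dg.fit_cell_type_model(ds)
    pred = model.predict("c", "stim")
    de = dg.point_prediction_de(pred, dg.group_mean(ds, "c", "0"))
    np.testing.assert_array_equal(de.lfc, 0.0)


@pytest.mark.filterwarnings("ignore:contexts without control")
def test_cell_type_model_errors_without_control_samples():
    with pytest.warns(UserWarning):
        ds = _dataset([("c", "stim"), ("c", "stim")], [[1.0], [2.0]])
    with pytest.raises(ValueError, match="control"):
        dg.fit_cell_type_model(ds)


def test_cell_type_model_auc_equals_prevalence_on_any_labeling(small_sc):
    """The degenerate predictor's AUC-PR is exactly the baseline π."""
    ds, truth = small_sc
    res = dg.benchmark_cell_level(ds, [("ct1", "stim")], models=("cell-type",))
    rep = res[("ct1", "stim")]["cell-type"]
    assert rep.auc_pr == pytest.approx(rep.baseline, abs=1e-15)


# ----------------------------------------------------------------------
# perturbation model


def test_perturbation_model_grand_mean_ignores_context():
    ds = _dataset(
        [("c1", "0"), ("c2", "0"), ("c1", "a"), ("c2", "a")],
        [[0.0, 0.0], [0.0, 0.0], [1.0, 3.0], [3.0, 5.0]],
    )
    model = dg.fit_perturbation_model(ds)
    np.testing.assert_allclose(model.predict("c1", "a"), [2.0, 4.0])
    np.testing.assert_allclose(model.predict("c2", "a"), [2.0, 4.0])


def test_perturbation_model_single_context_action_degenerates():
    ds = _dataset(
        [("c1", "0"), ("c2", "0"), ("c1", "a")],
        [[0.0], [0.0], [7.0]],
    )
    model = dg.fit_perturbation_model(ds)
    np.testing.assert_allclose(model.predict("c2", "a"), [7.0])


def test_perturbation_model_unseen_action_is_an_error():
    ds = _dataset([("c1", "0"), ("c1", "a")], [[1.0], [2.0]])
    model = dg.fit_perturbation_model(ds)
    with pytest.raises(ValueError, match="not observed"):
        model.predict("c1", "b")


def test_context_dominated_data_favors_cell_type_over_perturbation_model():
    """With strong context effects and no action effects, ignoring context
    costs the perturbation model R² relative to the cell-type model."""
    cfg = dg.pbmc_like_config(
        n_genes=300, n_contexts=4, cells_per_pair=40, deg_fraction=0.0, context_sd=1.0
    )
    ds, _ = dg.simulate_single_cell(cfg, seed=3)
    res = dg.benchmark_cell_level(
        ds, [("ct0", "stim")], models=("cell-type", "perturbation"),
        thresholds=DEThresholds(p_thr=0.5, l_thr=0.0),  # permissive: labels exist under the null
    )
    per = res[("ct0", "stim")]
    assert per["cell-type"].r2_all > per["perturbation"].r2_all


# ----------------------------------------------------------------------
# two-factor model


def _additive_dataset(alpha, beta, pairs, n_per=3, sigma=0.0, seed=0):
    """Cells generated exactly (or noisily) from alpha_c + beta_a."""
    rng = np.random.default_rng(seed)
    rows, blocks = [], []
    n_genes = alpha.shape[1]
    for c, a in pairs:
        mean = alpha[int(c[2:])] + (beta[int(a[1:])] if a != "0" else 0.0)
        cells = np.tile(mean, (n_per, 1))
        if sigma > 0:
            cells = cells + rng.normal(0, sigma, size=cells.shape)
        blocks.append(cells)
        rows += [(c, a)] * n_per
    return _dataset(rows, np.vstack(blocks))


def test_two_factor_recovers_noiseless_parameters_exactly():
    rng = np.random.default_rng(1)
    alpha = rng.uniform(1, 4, size=(3, 8))
    beta = np.vstack([np.zeros(8), rng.normal(0, 1, size=8)])  # beta[1] is action a1
    pairs = [(f"ct{c}", a) for c in range(3) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs)
    params = dg.fit_two_factor_model(ds)
    np.testing.assert_allclose(params.alpha, alpha, atol=1e-9)
    np.testing.assert_allclose(params.beta_for("a1"), beta[1], atol=1e-9)
    for c, a in pairs:
        np.testing.assert_allclose(
            dg.predict_two_factor(params, c, a),
            alpha[int(c[2:])] + (beta[1] if a == "a1" else 0.0),
            atol=1e-9,
        )


def test_two_factor_balanced_beta_is_mean_of_context_contrasts():
    # two contexts, one action, equal n: beta-hat = average over contexts of
    # (perturbed mean - control mean) on the fitting scale
    rng = np.random.default_rng(2)
    blocks, rows = [], []
    means = {}
    for c in ("ct0", "ct1"):
        for a in ("0", "a1"):
            m = rng.uniform(1, 3, size=5)
            means[(c, a)] = m
            blocks.append(np.tile(m, (4, 1)) + rng.normal(0, 0.01, size=(4, 5)))
            rows += [(c, a)] * 4
    ds = _dataset(rows, np.vstack(blocks))
    params = dg.fit_two_factor_model(ds)
    observed_contrast = np.mean(
        [
            ds.matrix[ds.mask(c, "a1")].mean(0) - ds.matrix[ds.mask(c, "0")].mean(0)
            for c in ("ct0", "ct1")
        ],
        axis=0,
    )
    np.testing.assert_allclose(params.beta_for("a1"), observed_contrast, atol=1e-9)


def test_two_factor_extrapolates_to_held_out_pair():
    rng = np.random.default_rng(3)
    alpha = rng.uniform(1, 4, size=(3, 6))
    beta = np.vstack([np.zeros(6), rng.normal(0, 1, size=6)])
    pairs = [(f"ct{c}", a) for c in range(3) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs)
    train, _ = dg.holdout_split(ds, held_out=[("ct0", "a1")])
    params = dg.fit_two_factor_model(ds, train)
    np.testing.assert_allclose(
        dg.predict_two_factor(params, "ct0", "a1"), alpha[0] + beta[1], atol=1e-9
    )


def test_two_factor_with_zero_beta_nests_the_cell_type_model():
    rng = np.random.default_rng(4)
    alpha = rng.uniform(1, 4, size=(2, 5))
    beta = np.zeros((2, 5))
    pairs = [(f"ct{c}", a) for c in range(2) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs)
    params = dg.fit_two_factor_model(ds)
    ct = dg.fit_cell_type_model(ds)
    for c in ("ct0", "ct1"):
        np.testing.assert_allclose(
            dg.predict_two_factor(params, c, "a1"), ct.predict(c, "a1"), atol=1e-9
        )


def test_two_factor_control_prediction_is_alpha_only():
    rng = np.random.default_rng(5)
    alpha = rng.uniform(1, 4, size=(2, 4))
    beta = np.vstack([np.zeros(4), rng.normal(size=4)])
    pairs = [(f"ct{c}", a) for c in range(2) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs)
    params = dg.fit_two_factor_model(ds)
    np.testing.assert_allclose(dg.predict_two_factor(params, "ct0", "0"), alpha[0], atol=1e-9)


@pytest.mark.filterwarnings("ignore:contexts without control")
def test_two_factor_confounded_design_is_rejected():
    # action only ever observed with ct1 and no other pairs for ct1
    with pytest.warns(UserWarning, match="without control"):
        ds = _dataset(
            [("ct0", "0"), ("ct0", "0"), ("ct1", "a1"), ("ct1", "a1")],
            np.random.default_rng(6).uniform(1, 2, (4, 3)),
        )
    with pytest.raises(ValueError, match="confounded|rank"):
        dg.fit_two_factor_model(ds)


# ----------------------------------------------------------------------
# two-factor DE test


def test_two_factor_null_pvalues_are_uniform():
    rng = np.random.default_rng(7)
    alpha = rng.uniform(1, 4, size=(3, 3000))
    beta = np.zeros((2, 3000))
    pairs = [(f"ct{c}", a) for c in range(3) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs, n_per=8, sigma=0.5, seed=8)
    params = dg.fit_two_factor_model(ds)
    de = dg.two_factor_de(params, "a1")
    ks = scipy.stats.kstest(de.pvalue, "uniform").statistic
    assert ks < 1.63 / np.sqrt(3000)


def test_two_factor_de_top_rank_and_sign_follow_beta():
    rng = np.random.default_rng(9)
    alpha = rng.uniform(2, 3, size=(2, 20))
    beta = np.zeros((2, 20))
    beta[1, 4] = 2.0
    beta[1, 11] = -1.0
    pairs = [(f"ct{c}", a) for c in range(2) for a in ("0", "a1")]
    ds = _additive_dataset(alpha, beta, pairs, n_per=10, sigma=0.01, seed=10)
    params = dg.fit_two_factor_model(ds)
    de = dg.two_factor_de(params, "a1")
    scores = dg.rank_scores(de)
    assert scores.argmax() == 4
    assert np.sign(de.lfc[4]) == 1 and np.sign(de.lfc[11]) == -1


def test_beta_rmse_shrinks_as_root_n():
    """RMSE(β̂) ~ n^(-1/2): log-log slope of -0.5 across n = 20, 80, 320."""
    ns = [20, 80, 320]
    rmses = []
    rng_truth = np.random.default_rng(11)
    alpha = rng_truth.uniform(1, 4, size=(3, 400))
    beta = np.vstack([np.zeros(400), rng_truth.normal(0, 0.5, size=400)])
    pairs = [(f"ct{c}", a) for c in range(3) for a in ("0", "a1")]
    for i, n in enumerate(ns):
        ds = _additive_dataset(alpha, beta, pairs, n_per=n, sigma=0.5, seed=100 + i)
        params = dg.fit_two_factor_model(ds)
        rmses.append(np.sqrt(np.mean((params.beta_for("a1") - beta[1]) ** 2)))
    slope = np.polyfit(np.log(ns), np.log(rmses), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)


# ----------------------------------------------------------------------
# sampled-prediction adapter


def test_sampled_predictions_from_control_distribution_yield_no_degs():
    rng = np.random.default_rng(12)
    control = rng.normal(3, 0.5, size=(60, 100))
    samples = rng.normal(3, 0.5, size=(60, 100))
    de = dg.sampled_prediction_de(samples, control)
    assert de.label.sum() <= 1  # essentially the null


def test_sampled_predictions_with_injected_shift_flag_the_gene():
    rng = np.random.default_rng(13)
    control = rng.normal(2, 0.2, size=(50, 20))
    samples = control.copy()
    samples[:, 7] = control[:, 7] * 2.0  # +1 log2 unit on gene 7
    de = dg.sampled_prediction_de(samples, control)
    assert de.label[7] == 1
    assert de.label.sum() == 1


def test_sampled_prediction_lfc_is_compositional():
    rng = np.random.default_rng(14)
    control = rng.uniform(1, 3, size=(10, 8))
    samples = rng.uniform(1, 3, size=(12, 8))
    de = dg.sampled_prediction_de(samples, control, pseudocount=1e-6)
    expected = dg.log2_fold_change(samples.mean(0), control.mean(0), 1e-6)
    np.testing.assert_array_equal(de.lfc, expected)


def test_sampled_prediction_needs_two_samples_each():
    with pytest.raises(ValueError, match=">= 2"):
        dg.sampled_prediction_de(np.ones((1, 3)), np.ones((5, 3)))
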