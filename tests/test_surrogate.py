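"""Nested cross-validation, model selection, and the ensemble fusions."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.neighbors import KNeighborsRegressor

from cfopt.surrogate import (
    CVReport,
    ModelSpec,
    default_registry,
    fit_average,
    fit_nnls,
    fit_stacking,
    fit_surrogate,
    nested_cv_evaluate,
    predict_ensemble,
    select_best,
    _pearson,
)


def linear_data(n=30, d=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, (n, d))
    w = np.arange(1, d + 1, dtype=float)
    y = 5.0 + X @ w + noise * rng.standard_normal(n)
    return X, y


def linear_registry():
    return [ModelSpec("linear", LinearRegression(), {"fit_intercept": [True]})]


def test_noiseless_linear_truth_is_realized():
    X, y = linear_data()
    report = nested_cv_evaluate(X, y, linear_registry(), seed=3)
    assert report.mean_correlation("linear") == pytest.approx(1.0, abs=1e-6)
    assert report.mean_r2("linear") == pytest.approx(1.0, abs=1e-6)


def test_default_fold_counts_are_nine_outer_three_inner():
    X, y = linear_data(n=20)
    report = nested_cv_evaluate(X, y, linear_registry())
    assert report.outer_folds == 9
    assert report.inner_folds == 3
    assert len(report.fold_correlations["linear"]) == 9


def test_outer_scores_match_manual_double_loop():
    """Independent re-implementation of the nested loop over the same
    fold indices reproduces every outer-fold correlation."""
    X, y = linear_data(n=27, noise=1.0, seed=5)
    spec = ModelSpec("knn", KNeighborsRegressor(), {"n_neighbors": [2, 4]})
    seed = 11
    report = nested_cv_evaluate(X, y, [spec], outer_folds=9, inner_folds=3,
                                seed=seed)

    manual = []
    outer = KFold(9, shuffle=True, random_state=seed)
    for fold_idx, (tr, te) in enumerate(outer.split(X)):
        best_p, best_s = None, -np.inf
        inner = KFold(3, shuffle=True, random_state=seed * 1000 + fold_idx)
        inner_splits = list(inner.split(X[tr]))
        for params in ParameterGrid(spec.grid):
            scores = []
            for itr, ite in inner_splits:
                m = KNeighborsRegressor(**params).fit(X[tr][itr], y[tr][itr])
                scores.append(_pearson(y[tr][ite], m.predict(X[tr][ite])))
            if np.mean(scores) > best_s:
                best_p, best_s = params, float(np.mean(scores))
        m = KNeighborsRegressor(**best_p).fit(X[tr], y[tr])
        manual.append(_pearson(y[te], m.predict(X[te])))
    assert np.allclose(report.fold_correlations["knn"], manual, atol=1e-12)


def test_no_leakage_from_held_out_responses():
    """Corrupting a held-out fold's responses must not change the
    hyperparameters chosen for that fold (metamorphic check)."""
    X, y = linear_data(n=27, noise=2.0, seed=8)
    spec = ModelSpec("knn", KNeighborsRegressor(), {"n_neighbors": [2, 5]})
    report = nested_cv_evaluate(X, y, [spec], seed=4)
    outer = KFold(9, shuffle=True, random_state=4)
    te0 = list(outer.split(X))[0][1]
    y_bad = y.copy()
    y_bad[te0] = 1e6  # garbage in the first held-out fold
    report_bad = nested_cv_evaluate(X, y_bad, [spec], seed=4)
    assert report.chosen_params["knn"][0] == report_bad.chosen_params["knn"][0]


def test_select_best_argmax_and_ties():
    report = CVReport(
        model_ids=["a", "b", "c"],
        fold_correlations={"a": [0.7], "b": [0.9], "c": [0.9]},
        fold_r2={"a": [0.5], "b": [0.8], "c": [0.8]},
        chosen_params={"a": [{}], "b": [{}], "c": [{}]},
        outer_folds=1, inner_folds=3, seed=0,
    )
    assert select_best(report) == "b"  # argmax; tie with c -> first
    scores = [report.mean_correlation(m) for m in report.model_ids]
    assert report.model_ids[int(np.argmax(scores))] == "b"


def test_single_model_registry_selected():
    X, y = linear_data(n=12)
    report = nested_cv_evaluate(X, y, linear_registry(), outer_folds=3)
    assert report.selected_model_id == "linear"


def test_determinism_same_seed_identical_report():
    X, y = linear_data(n=24, noise=1.5, seed=2)
    reg = [ModelSpec("knn", KNeighborsRegressor(), {"n_neighbors": [2, 4]})]
    a = nested_cv_evaluate(X, y, reg, seed=9)
    b = nested_cv_evaluate(X, y, reg, seed=9)
    assert a.fold_correlations == b.fold_correlations
    assert a.chosen_params == b.chosen_params


# -- fusions --------------------------------------------------------------


def test_nnls_perfect_base_gets_weight_one():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    w = fit_nnls(y[:, None], y)
    assert w.weights[0] == pytest.approx(1.0, abs=1e-9)
    resid = y - predict_ensemble(w, y[:, None])
    assert np.allclose(resid, 0.0, atol=1e-9)


def test_nnls_anticorrelated_base_clamped_to_zero():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    w = fit_nnls(-y[:, None], y)
    assert w.weights[0] == 0.0


def test_nnls_matches_dense_grid_search():
    """Two-model objective within 1e-3 of a dense nonnegative grid."""
    rng = np.random.default_rng(3)
    P = rng.uniform(0, 10, (40, 2))
    y = 0.7 * P[:, 0] + 0.2 * P[:, 1] + rng.standard_normal(40)
    w = fit_nnls(P, y)
    obj = float(((y - P @ w.weights) ** 2).sum())
    grid = np.linspace(0, 2, 201)
    best = min(
        float(((y - P @ np.array([a, b])) ** 2).sum())
        for a in grid for b in grid
    )
    assert obj <= best + 1e-3


def test_nnls_never_worse_than_averaging():
    rng = np.random.default_rng(12)
    for _ in range(10):
        P = rng.uniform(-5, 5, (30, 3))
        y = rng.uniform(-5, 5, 30)
        nnls_obj = float(((y - predict_ensemble(fit_nnls(P, y), P)) ** 2).sum())
        avg_obj = float(((y - predict_ensemble(fit_average(3), P)) ** 2).sum())
        assert nnls_obj <= avg_obj + 1e-9


def test_stacking_constant_response_predicts_constant():
    P = np.random.default_rng(0).uniform(0, 1, (20, 3))
    y = np.full(20, 7.5)
    w = fit_stacking(P, y)
    pred = predict_ensemble(w, np.random.default_rng(1).uniform(0, 1, (5, 3)))
    assert np.allclose(pred, 7.5, atol=1e-6)


def test_stacking_single_perfect_base_recovers_identity():
    y = np.linspace(0, 50, 30)
    w = fit_stacking(y[:, None], y, penalty_grid=(1e-8, 1e-3))
    assert w.weights[0] == pytest.approx(1.0, abs=1e-3)
    assert w.intercept == pytest.approx(0.0, abs=1e-2)


def test_stacking_duplicated_bases_share_weight():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 10, 25)
    y = 2 * p + rng.standard_normal(25)
    w = fit_stacking(np.column_stack([p, p]), y)
    assert w.weights[0] == pytest.approx(w.weights[1], rel=1e-6)


def test_averaging_identities():
    assert np.allclose(fit_average(4).weights, 0.25)
    P = np.array([[10.0, 20.0]])
    assert predict_ensemble(fit_average(2), P)[0] == pytest.approx(15.0)
    # identical bases: ensemble equals the base
    P = np.tile(np.arange(5.0)[:, None], (1, 3))
    assert np.allclose(predict_ensemble(fit_average(3), P), np.arange(5.0))


def test_predict_ensemble_matches_matrix_product():
    rng = np.random.default_rng(6)
    P = rng.uniform(0, 1, (8, 3))
    from cfopt.surrogate import EnsembleWeights

    w = EnsembleWeights("stacking", np.array([0.2, 0.5, 0.1]), 3.0)
    assert np.allclose(predict_ensemble(w, P), P @ w.weights + 3.0)


def test_weight_count_mismatch_raises():
    with pytest.raises(ValueError):
        predict_ensemble(fit_average(2), np.ones((4, 3)))


def test_default_registry_has_seven_seeded_families():
    reg = default_registry(seed=5)
    assert len(reg) == 7
    assert len({s.model_id for s in reg}) == 7


def test_fit_surrogate_deterministic(cheap_registry):
    X, y = linear_data(n=20, noise=1.0, seed=3)
    a = fit_surrogate(X, y, registry=cheap_registry, outer_folds=5, seed=2)
    b = fit_surrogate(X, y, registry=cheap_registry, outer_folds=5, seed=2)
    Xq = np.random.default_rng(0).uniform(-1, 1, (6, 4))
    ma, sa = a.predict(Xq)
    mb, sb = b.predict(Xq)
    assert np.array_equal(ma, mb) and np.array_equal(sa, sb)
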