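"""Screening design generation, effect estimation, and the first-order
coded-model fit."""

import numpy as np
import pytest

import cfopt
from cfopt import (
    PBDesign,
    estimate_effects,
    fit_first_order,
    generate_pb_design,
    predict_first_order,
    select_significant,
)
from cfopt.screening import DesignError


def split_sum_effects(matrix, y):
    """Independent oracle: sum over +1 rows minus sum over -1 rows, / N."""
    out = []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        out.append((y[col > 0].sum() - y[col < 0].sum()) / len(y))
    return np.array(out)


@pytest.mark.parametrize("n_runs", [8, 12, 16, 20, 24])
def test_generated_designs_balanced_and_orthogonal(n_runs):
    design = generate_pb_design(n_factors=n_runs - 1, n_runs=n_runs)
    assert design.matrix.shape == (n_runs, n_runs - 1)
    assert design.is_balanced()
    # brute-force pairwise dot products
    m = design.matrix
    for i in range(m.shape[1]):
        for j in range(i + 1, m.shape[1]):
            assert float(m[:, i] @ m[:, j]) == 0.0
    assert (m == -1).all(axis=1).any()  # one all-minus run


def test_design_20x13_matches_screening_shape():
    design = generate_pb_design(13, 20)
    assert design.matrix.shape == (20, 13)
    assert design.is_orthogonal()


def test_unsupported_design_sizes():
    with pytest.raises(DesignError):
        generate_pb_design(5, 10)
    with pytest.raises(DesignError):
        generate_pb_design(20, 20)


def test_constant_response_gives_zero_effects():
    design = generate_pb_design(7, 8)
    eff = estimate_effects(design, np.full(8, 42.0))
    assert np.allclose(eff, 0.0)


def test_effect_recovers_single_column_signal():
    design = generate_pb_design(7, 8)
    y = design.matrix[:, 0].copy()
    eff = estimate_effects(design, y)
    assert eff[0] == pytest.approx(1.0)
    assert np.allclose(eff[1:], 0.0, atol=1e-12)


def test_effects_match_split_sum_oracle(pb_design, pb_runs):
    eff = estimate_effects(pb_design, pb_runs.responses)
    oracle = split_sum_effects(pb_design.matrix, pb_runs.responses)
    assert np.allclose(eff, oracle, atol=1e-12)


def test_ols_equals_split_sum_on_balanced_designs():
    """Coded OLS slope == split-sum effect and intercept == grand mean."""
    rng = np.random.default_rng(5)
    for n_runs, n_factors in [(8, 6), (12, 8), (20, 13)]:
        design = generate_pb_design(n_factors, n_runs)
        y = rng.uniform(0, 100, n_runs)
        fit = fit_first_order(design, y)
        assert np.allclose(fit.coefficients, split_sum_effects(design.matrix, y),
                           atol=1e-9)
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-9)
        assert fit.residual_df == n_runs - n_factors - 1


def test_noiseless_linear_model_recovered_exactly():
    design = generate_pb_design(13, 20)
    beta, coefs = 38.5, np.linspace(-9, 9, 13)
    y = beta + design.matrix @ coefs
    fit = fit_first_order(design, y)
    assert np.allclose(fit.coefficients, coefs, atol=1e-10)
    assert fit.intercept == pytest.approx(beta, abs=1e-10)


def test_run_order_permutation_invariance(pb_design, pb_runs):
    rng = np.random.default_rng(3)
    perm = rng.permutation(20)
    shuffled = PBDesign(pb_design.matrix[perm], tuple(range(1, 21)))
    a = fit_first_order(pb_design, pb_runs.responses)
    b = fit_first_order(shuffled, pb_runs.responses[perm])
    assert np.allclose(a.coefficients, b.coefficients)
    assert np.allclose(a.p_values, b.p_values)


def test_p_values_invariant_under_affine_response_rescale(pb_design, pb_runs):
    y = pb_runs.responses
    a = fit_first_order(pb_design, y)
    b = fit_first_order(pb_design, 3.7 * y + 11.0)
    assert np.allclose(a.p_values, b.p_values, atol=1e-12)
    assert np.allclose(a.t_values, b.t_values, atol=1e-12)


def test_significant_factors_from_measured_screening(pb_fit):
    """The five factors that matter: both enzyme loadings at the head of
    the pathway branch, the reductase, pH, and reaction volume."""
    assert select_significant(pb_fit, 0.05) == [
        "ZmPAL", "GmCHS", "MsCHR", "pH", "volume",
    ]
    assert select_significant(pb_fit, 0.0) == []
    assert len(select_significant(pb_fit, 1.0)) == 13


def test_recomputed_p_values_match_printed_to_printed_precision(pb_fit):
    printed = cfopt.load_fixture("pb_screening")
    assert np.allclose(np.round(pb_fit.p_values, 3), printed.p_values,
                       atol=1e-9)


def test_predict_center_is_intercept_and_linearity(pb_fit):
    z = np.zeros(13)
    assert predict_first_order(pb_fit, z) == pytest.approx(pb_fit.intercept)
    rng = np.random.default_rng(9)
    a, b = rng.normal(size=13), rng.normal(size=13)
    lhs = (predict_first_order(pb_fit, a) + predict_first_order(pb_fit, b)
           - pb_fit.intercept)
    assert lhs == pytest.approx(predict_first_order(pb_fit, a + b), rel=1e-9)


def test_predict_matches_dot_product_oracle(pb_fit):
    rng = np.random.default_rng(21)
    for _ in range(50):
        x = rng.uniform(-2, 2, 13)
        expected = pb_fit.intercept + float(np.dot(pb_fit.coefficients, x))
        assert predict_first_order(pb_fit, x) == pytest.approx(expected,
                                                               rel=1e-12)


def test_rank_deficient_rejected():
    m = np.ones((8, 2))
    m[:4, 0] = -1
    m[:, 1] = m[:, 0]  # duplicated column
    with pytest.raises(DesignError):
        fit_first_order(PBDesign(m, tuple(range(8))), np.arange(8.0))
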