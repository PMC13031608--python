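"""Shapley attribution: axioms under exact enumeration, convergence of
the sampled estimator, and the summary/waterfall outputs."""

import numpy as np
import pytest

from cfopt.attribution import (
    shapley_exact,
    shapley_sampled,
    summarize_attributions,
    waterfall_data,
)


def linear_model(weights):
    w = np.asarray(weights, dtype=float)
    return lambda X: np.atleast_2d(X) @ w


def interaction_model(X):
    X = np.atleast_2d(X)
    return 3 * X[:, 0] + 2 * X[:, 1] - X[:, 2] + 4 * X[:, 0] * X[:, 1]


@pytest.fixture
def background():
    return np.random.default_rng(0).uniform(-1, 1, (16, 5))


def test_linear_model_contributions_are_centered_terms(background):
    """For f(x) = sum a_i x_i the exact value of feature i is
    a_i (x_i - mean background_i)."""
    w = np.array([2.0, -1.0, 0.5, 0.0, 3.0])
    inst = np.array([0.4, -0.2, 0.9, 0.5, -0.7])
    res = shapley_exact(linear_model(w), inst, background)
    expected = w * (inst - background.mean(axis=0))
    assert np.allclose(res.values, expected, atol=1e-9)


def test_dummy_feature_gets_zero(background):
    w = np.array([1.0, 0.0, 2.0, 0.0, 0.0])
    inst = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
    res = shapley_exact(linear_model(w), inst, background)
    assert res.contributions["f1"] == pytest.approx(0.0, abs=1e-12)
    assert res.contributions["f3"] == pytest.approx(0.0, abs=1e-12)


def test_efficiency_axiom_exact_with_interactions():
    rng = np.random.default_rng(5)
    bg = rng.uniform(-1, 1, (20, 3))
    for _ in range(10):
        inst = rng.uniform(-1, 1, 3)
        res = shapley_exact(interaction_model, inst, bg)
        assert res.base_value + res.values.sum() == pytest.approx(
            res.prediction, abs=1e-9
        )


def test_symmetry_axiom_exact():
    """Two features entering identically with identical values get
    identical attributions."""
    model = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1] + \
        np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
    rng = np.random.default_rng(8)
    bg = rng.uniform(-1, 1, (15, 1))
    bg = np.column_stack([bg, bg])  # symmetric background too
    res = shapley_exact(model, np.array([0.7, 0.7]), bg)
    assert res.contributions["f0"] == pytest.approx(res.contributions["f1"],
                                                    abs=1e-12)


def test_feature_limit_directs_to_sampler():
    with pytest.raises(ValueError, match="shapley_sampled"):
        shapley_exact(lambda X: np.atleast_2d(X).sum(axis=1),
                      np.zeros(13), np.zeros((4, 13)))


def test_sampled_same_seed_identical(background):
    inst = np.full(5, 0.3)
    a = shapley_sampled(interaction_model_5, inst, background, 200, seed=4)
    b = shapley_sampled(interaction_model_5, inst, background, 200, seed=4)
    assert a.contributions == b.contributions


def interaction_model_5(X):
    X = np.atleast_2d(X)
    return (2 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2] * X[:, 3]
            + np.sin(X[:, 4]) + X[:, 0] * X[:, 2])


def test_sampled_converges_to_exact(background):
    """Three permutation budgets: error shrinks toward the enumeration."""
    rng = np.random.default_rng(2)
    inst = rng.uniform(-1, 1, 5)
    exact = shapley_exact(interaction_model_5, inst, background)
    errors = []
    for n in (50, 500, 5000):
        s = shapley_sampled(interaction_model_5, inst, background, n, seed=0)
        errors.append(float(np.abs(s.values - exact.values).max()))
    assert errors[-1] <= errors[0] + 1e-12
    assert errors[0] < 0.5 and errors[1] < 0.1 and errors[-1] < 0.02


def test_sampled_symmetric_features_close(background):
    model = lambda X: np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
    bg = background.copy()
    bg[:, 1] = bg[:, 0]
    res = shapley_sampled(model, np.array([0.5, 0.5, 0.0, 0.0, 0.0]), bg,
                          2000, seed=1)
    assert res.contributions["f0"] == pytest.approx(
        res.contributions["f1"], abs=5 * res.mc_tolerance + 1e-6
    )


def test_summary_ranks_dominant_synthetic_factor():
    """On a landscape whose dominant factor is the PAL-enzyme analog,
    that factor ranks first by mean |contribution|."""
    import cfopt

    oracle = cfopt.make_oracle(seed=1)
    space = oracle.config.space
    names = space.names
    keep = ["ZmPAL", "ATP", "time"]  # dominant + two mild factors
    center = {n: space[n].center for n in names}

    def model(X):
        X = np.atleast_2d(X)
        rows = []
        for r in X:
            s = dict(center)
            for n, v in zip(keep, r):
                s[n] = space[n].center + v * space[n].half_range
            rows.append(s)
        return oracle.noiseless(rows)

    rng = np.random.default_rng(3)
    bg = rng.uniform(-1, 1, (12, 3))
    results = [
        shapley_exact(model, inst, bg, feature_names=keep)
        for inst in rng.uniform(-1, 1, (8, 3))
    ]
    summary = summarize_attributions(results)
    top = next(s for s in summary if s["rank"] == 1)
    assert top["feature"] == "ZmPAL"


def test_summary_rank_invariant_under_feature_permutation(background):
    rng = np.random.default_rng(7)
    instances = rng.uniform(-1, 1, (6, 5))
    res = [shapley_exact(interaction_model_5, i, background) for i in instances]
    summary = {s["feature"]: s["rank"] for s in summarize_attributions(res)}

    perm = [4, 2, 0, 3, 1]
    model_p = lambda X: interaction_model_5(np.atleast_2d(X)[:, np.argsort(perm)])
    res_p = [
        shapley_exact(model_p, i[perm], background[:, perm],
                      feature_names=[f"f{j}" for j in perm])
        for i in instances
    ]
    summary_p = {s["feature"]: s["rank"] for s in summarize_attributions(res_p)}
    assert summary == summary_p


def test_all_zero_contributions_reported_missing(background):
    const = lambda X: np.full(np.atleast_2d(X).shape[0], 3.0)
    res = [shapley_exact(const, np.zeros(5), background) for _ in range(3)]
    summary = summarize_attributions(res)
    assert all(s["sign_association"] is None for s in summary)
    assert all(s["mean_abs_contribution"] == 0.0 for s in summary)


def test_waterfall_walks_from_base_to_prediction(background):
    rng = np.random.default_rng(11)
    for _ in range(10):
        inst = rng.uniform(-1, 1, 5)
        res = shapley_exact(interaction_model_5, inst, background)
        steps = waterfall_data(res)
        mags = [abs(s["contribution"]) for s in steps]
        assert mags == sorted(mags, reverse=True)
        assert steps[-1]["cumulative"] == pytest.approx(res.prediction,
                                                        abs=1e-9)


def test_waterfall_tiny_example():
    model = linear_model(np.array([1.0, 1.0]))
    bg = np.array([[0.0, 0.0]])
    res = shapley_exact(model, np.array([2.0, -1.0]), bg)
    steps = waterfall_data(res)
    assert [s["contribution"] for s in steps] == pytest.approx([2.0, -1.0])
    assert [s["cumulative"] for s in steps] == pytest.approx([2.0, 1.0])
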