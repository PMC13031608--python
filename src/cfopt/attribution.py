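"""Shapley-value feature attribution for fitted surrogates.

One prediction is decomposed into per-feature contributions relative
to a *base value* (the mean prediction over a background sample,
normally the current training set).  The value of a feature coalition
S is the interventional marginal expectation

    v(S) = E_b[ f(x_S, b_notS) ]

— coalition features fixed at the explained instance, the rest drawn
from the background.  Exact enumeration over all 2^d coalitions is used
for small d; a permutation-sampling estimator (with antithetic
permutation pairs for variance reduction) covers larger feature counts.
The exact path satisfies the efficiency (base + sum of contributions =
prediction), dummy, and symmetry axioms to numerical precision, and the
sampled path converges to it as the permutation budget grows.

Outputs map onto the standard visual summaries: per-feature importance
rankings with the sign of the feature-contribution association
(summary-plot data) and ordered cumulative walks from base value to
prediction (waterfall-plot data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "AttributionResult",
    "shapley_exact",
    "shapley_sampled",
    "summarize_attributions",
    "waterfall_data",
]

EXACT_MAX_FEATURES = 12


def _as_predictor(model) -> Callable[[np.ndarray], np.ndarray]:
    if hasattr(model, "predict"):
        return lambda X: np.asarray(model.predict(X), dtype=float).ravel()
    return lambda X: np.asarray(model(X), dtype=float).ravel()


@dataclass
class AttributionResult:
    """Per-instance Shapley decomposition."""

    feature_names: list[str]
    instance: np.ndarray
    base_value: float
    contributions: dict[str, float]
    prediction: float
    method: str  # exact | sampled
    n_permutations: int = 0
    seed: int | None = None
    mc_tolerance: float = 0.0  # ~2 standard errors of the MC estimate

    @property
    def values(self) -> np.ndarray:
        return np.array([self.contributions[n] for n in self.feature_names])


def _coalition_values(
    predict, instance: np.ndarray, background: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """v(S) for each boolean mask row: mean over the background of the
    model at (instance where mask, background elsewhere)."""
    n_bg, d = background.shape
    n_masks = masks.shape[0]
    # tile: for each mask, n_bg hybrid rows
    X = np.repeat(background[None, :, :], n_masks, axis=0)  # (m, n_bg, d)
    X[masks[:, None, :].repeat(n_bg, axis=1)] = np.broadcast_to(
        instance, (n_masks, n_bg, d)
    )[masks[:, None, :].repeat(n_bg, axis=1)]
    preds = predict(X.reshape(n_masks * n_bg, d))
    return preds.reshape(n_masks, n_bg).mean(axis=1)


def shapley_exact(
    model,
    instance: Sequence[float],
    background: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Exact Shapley values by enumeration over all 2^d coalitions.

    Limited to ``d <= 12`` (the enumeration grows as 2^d x background
    size); call :func:`shapley_sampled` beyond that.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = instance.size
    if d > EXACT_MAX_FEATURES:
        raise ValueError(
            f"{d} features exceeds the exact-enumeration limit "
            f"({EXACT_MAX_FEATURES}); use shapley_sampled"
        )
    if background.shape[1] != d:
        raise ValueError("background feature count differs from instance")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(d)]
    predict = _as_predictor(model)

    masks = np.array(
        [[(m >> i) & 1 for i in range(d)] for m in range(2**d)], dtype=bool
    )
    v = _coalition_values(predict, instance, background, masks)
    sizes = masks.sum(axis=1)
    # Shapley kernel weights w(|S|) = |S|! (d-|S|-1)! / d!
    w = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros(d)
    for i in range(d):
        without = ~masks[:, i]
        idx_without = np.nonzero(without)[0]
        idx_with = idx_without | (1 << i)  # mask bit arithmetic on indices
        phi[i] = float(
            np.sum(w[sizes[idx_without]] * (v[idx_with] - v[idx_without]))
        )
    base = float(v[0])
    pred = float(predict(instance[None, :])[0])
    return AttributionResult(
        feature_names=names,
        instance=instance,
        base_value=base,
        contributions={n: float(p) for n, p in zip(names, phi)},
        prediction=pred,
        method="exact",
    )


def shapley_sampled(
    model,
    instance: Sequence[float],
    background: np.ndarray,
    n_permutations: int = 2000,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Permutation-sampling Shapley estimator, antithetic pairs.

    Each sampled permutation contributes one marginal-gain walk from
    the empty coalition to the full one; its reversal is evaluated too,
    which cancels much of the walk-order noise.  Deterministic given
    ``seed``; ``mc_tolerance`` reports ~2 standard errors of the
    per-feature estimate.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background sample is empty")
    d = instance.size
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(d)]
    predict = _as_predictor(model)
    rng = np.random.default_rng(seed)

    perms = []
    while len(perms) < n_permutations:
        p = rng.permutation(d)
        perms.append(p)
        if len(perms) < n_permutations:
            perms.append(p[::-1].copy())  # antithetic partner

    n_bg = background.shape[0]
    contrib_samples = np.zeros((len(perms), d))
    # chunk permutations so each predict call stays a few 10^4 rows
    chunk = max(1, int(2e4 // ((d + 1) * n_bg)) or 1)
    for start in range(0, len(perms), chunk):
        block = perms[start : start + chunk]
        masks = []
        for p in block:
            m = np.zeros((d + 1, d), dtype=bool)
            for j, feat in enumerate(p):
                m[j + 1] = m[j]
                m[j + 1, feat] = True
            masks.append(m)
        masks = np.vstack(masks)  # (len(block)*(d+1), d)
        v = _coalition_values(predict, instance, background, masks)
        v = v.reshape(len(block), d + 1)
        for bi, p in enumerate(block):
            gains = np.diff(v[bi])
            contrib_samples[start + bi, p] = gains

    phi = contrib_samples.mean(axis=0)
    se = contrib_samples.std(axis=0, ddof=1) / np.sqrt(len(perms)) if len(perms) > 1 else np.zeros(d)
    base = float(predict(background).mean())
    pred = float(predict(instance[None, :])[0])
    return AttributionResult(
        feature_names=names,
        instance=instance,
        base_value=base,
        contributions={n: float(p) for n, p in zip(names, phi)},
        prediction=pred,
        method="sampled",
        n_permutations=len(perms),
        seed=seed,
        mc_tolerance=float(2.0 * se.max()),
    )


def summarize_attributions(results: Sequence[AttributionResult]) -> list[dict]:
    """Summary-plot data: per-feature mean |contribution|, rank, and the
    correlation between feature value and contribution across instances
    (positive = larger values push predictions up).

    Ranks are 1-based, largest mean |contribution| first; the
    association is reported as ``None`` when it is undefined (constant
    contributions or a single instance).
    """
    if not results:
        raise ValueError("need at least one attribution result")
    names = results[0].feature_names
    vals = np.array([r.values for r in results])  # (n, d)
    feats = np.array([r.instance for r in results])
    mean_abs = np.abs(vals).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    ranks = np.empty(len(names), dtype=int)
    ranks[order] = np.arange(1, len(names) + 1)
    out = []
    for j, name in enumerate(names):
        if len(results) < 2 or vals[:, j].std() == 0 or feats[:, j].std() == 0:
            assoc = None
        else:
            assoc = float(np.corrcoef(feats[:, j], vals[:, j])[0, 1])
        out.append(
            {
                "feature": name,
                "mean_abs_contribution": float(mean_abs[j]),
                "rank": int(ranks[j]),
                "sign_association": assoc,
            }
        )
    return out


def waterfall_data(result: AttributionResult) -> list[dict]:
    """Waterfall-plot data: features by |contribution| descending with
    the cumulative partial sums walking from the base value to the
    prediction."""
    order = np.argsort(-np.abs(result.values), kind="stable")
    cum = result.base_value
    steps = []
    for j in order:
        name = result.feature_names[j]
        c = result.contributions[name]
        cum += c
        steps.append({"feature": name, "contribution": float(c),
                      "cumulative": float(cum)})
    return steps
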