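"""Surrogate modeling: a seven-regressor zoo evaluated by nested
cross-validation, with stacking / averaging / non-negative least
squares ensemble fusions.

Small-data regression (tens of runs, ~13 coded features) is the regime
here, so generalization is estimated by *nested* cross-validation: an
inner 3-fold grid search picks hyperparameters using the training
portion only, and an outer 9-fold loop scores the tuned model on runs
it never saw.  The surrogate actually used for optimization is the
model family with the best mean held-out Pearson correlation; the three
fusions combine all base families and are reported alongside.

Registry families (all seeded, all pluggable):

* random forest, RBF-kernel support vector regression, multilayer
  perceptron, Gaussian-process regression (Matern kernel), and three
  gradient-boosted-tree configurations (xgboost, lightgbm, and the
  scikit-learn gradient-boosting implementation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize as _sciopt
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    Matern,
    WhiteKernel,
)
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

__all__ = [
    "ModelSpec",
    "CVReport",
    "EnsembleWeights",
    "default_registry",
    "nested_cv_evaluate",
    "select_best",
    "fit_nnls",
    "fit_stacking",
    "fit_average",
    "predict_ensemble",
    "Surrogate",
    "fit_surrogate",
]


@dataclass
class ModelSpec:
    """One model family: a seeded estimator plus a small tuning grid."""

    model_id: str
    estimator: object
    grid: dict[str, list]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError(f"{self.model_id}: hyperparameter grid is empty")


@dataclass
class CVReport:
    """Nested-CV outcome for every registry family."""

    model_ids: list[str]
    fold_correlations: dict[str, list[float]]
    fold_r2: dict[str, list[float]]
    chosen_params: dict[str, list[dict]]
    outer_folds: int
    inner_folds: int
    seed: int
    selected_model_id: str = ""

    def mean_correlation(self, model_id: str) -> float:
        return float(np.mean(self.fold_correlations[model_id]))

    def mean_r2(self, model_id: str) -> float:
        return float(np.mean(self.fold_r2[model_id]))

    def to_dict(self) -> dict:
        return {
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "seed": self.seed,
            "selected_model_id": self.selected_model_id,
            "models": {
                m: {
                    "fold_correlations": list(map(float, self.fold_correlations[m])),
                    "fold_r2": list(map(float, self.fold_r2[m])),
                    "mean_correlation": self.mean_correlation(m),
                    "mean_r2": self.mean_r2(m),
                    "chosen_params": self.chosen_params[m],
                }
                for m in self.model_ids
            },
        }


@dataclass
class EnsembleWeights:
    """Linear fusion of base-model predictions."""

    method: str  # stacking | averaging | nnls
    weights: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.method not in ("stacking", "averaging", "nnls"):
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if self.method == "nnls" and (self.weights < 0).any():
            raise ValueError("nnls weights must be non-negative")


def default_registry(seed: int = 0) -> list[ModelSpec]:
    """Seven seeded families with small grids sized for tens of runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import lightgbm
        import xgboost

    gp_kernel = ConstantKernel(1.0, (1e-2, 1e3)) * Matern(
        length_scale=1.0, length_scale_bounds=(0.1, 20.0), nu=2.5
    ) + WhiteKernel(1e-2, (1e-6, 1e2))
    return [
        ModelSpec(
            "random-forest",
            RandomForestRegressor(n_estimators=50, random_state=seed, n_jobs=1),
            {"max_features": [0.5, 1.0]},
            seed,
        ),
        ModelSpec(
            "kernel-support-vector",
            SVR(kernel="rbf", gamma="scale"),
            {"C": [1.0, 10.0, 100.0], "epsilon": [0.5, 2.0]},
            seed,
        ),
        ModelSpec(
            "multilayer-perceptron",
            MLPRegressor(
                hidden_layer_sizes=(8,),
                solver="lbfgs",
                max_iter=200,
                random_state=seed,
            ),
            {"alpha": [1e-2, 1.0]},
            seed,
        ),
        ModelSpec(
            "gradient-boosted-trees-A",
            xgboost.XGBRegressor(
                n_estimators=80,
                learning_rate=0.08,
                max_depth=3,
                subsample=0.9,
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
            {"max_depth": [2, 3], "learning_rate": [0.05, 0.1]},
            seed,
        ),
        ModelSpec(
            "gradient-boosted-trees-B",
            lightgbm.LGBMRegressor(
                n_estimators=80,
                learning_rate=0.08,
                num_leaves=7,
                min_child_samples=3,
                random_state=seed,
                deterministic=True,
                force_col_wise=True,
                n_jobs=1,
                verbose=-1,
            ),
            {"num_leaves": [3, 7], "learning_rate": [0.05, 0.1]},
            seed,
        ),
        ModelSpec(
            "gradient-boosted-trees-C",
            GradientBoostingRegressor(n_estimators=60, max_depth=2,
                                      random_state=seed),
            {"learning_rate": [0.05, 0.1]},
            seed,
        ),
        ModelSpec(
            "gaussian-process",
            GaussianProcessRegressor(
                kernel=gp_kernel,
                normalize_y=True,
                n_restarts_optimizer=0,
                random_state=seed,
            ),
            {"alpha": [1e-10, 1e-6]},
            seed,
        ),
    ]


def _pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson r; 0 when either side is (numerically) constant."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.std() == 0 or y_pred.std() == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, float)
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    sse = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0


def _fit_predict(est, params, X_tr, y_tr, X_te) -> np.ndarray:
    model = clone(est)
    model.set_params(**params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_tr, y_tr)
        return np.asarray(model.predict(X_te), dtype=float)


def _inner_search(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, inner_folds: int, seed: int
) -> dict:
    """Grid search by inner-CV mean Pearson correlation; ties break
    toward the first grid point (stable ParameterGrid order)."""
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_params, best_score = None, -np.inf
    for params in ParameterGrid(spec.grid):
        scores = []
        for tr, te in splits:
            pred = _fit_predict(spec.estimator, params, X[tr], y[tr], X[te])
            scores.append(_pearson(y[te], pred))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def nested_cv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    registry: Sequence[ModelSpec],
    outer_folds: int = 9,
    inner_folds: int = 3,
    seed: int = 0,
) -> CVReport:
    """Nested cross-validation over the registry.

    For each outer fold the inner grid search sees *only* the outer
    training portion; held-out Pearson correlation and R-squared are
    recorded per fold.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < outer_folds:
        raise ValueError(
            f"need at least outer_folds={outer_folds} rows, got {len(X)}"
        )
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    splits = list(outer.split(X))
    report = CVReport(
        model_ids=[s.model_id for s in registry],
        fold_correlations={s.model_id: [] for s in registry},
        fold_r2={s.model_id: [] for s in registry},
        chosen_params={s.model_id: [] for s in registry},
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        seed=seed,
    )
    for spec in registry:
        for fold_idx, (tr, te) in enumerate(splits):
            params = _inner_search(
                spec, X[tr], y[tr], inner_folds, seed=seed * 1000 + fold_idx
            )
            pred = _fit_predict(spec.estimator, params, X[tr], y[tr], X[te])
            report.fold_correlations[spec.model_id].append(_pearson(y[te], pred))
            report.fold_r2[spec.model_id].append(_r2(y[te], pred))
            report.chosen_params[spec.model_id].append(params)
    report.selected_model_id = select_best(report)
    return report


def select_best(report: CVReport) -> str:
    """Model with the highest mean held-out correlation; ties go to the
    earliest registry entry."""
    if not report.model_ids:
        raise ValueError("empty report")
    scores = [report.mean_correlation(m) for m in report.model_ids]
    return report.model_ids[int(np.argmax(scores))]


# -- ensemble fusions -----------------------------------------------------


def fit_nnls(base_predictions: np.ndarray, responses: Sequence[float]) -> EnsembleWeights:
    """Non-negative least-squares fusion (no intercept, no sum-to-one)."""
    P = np.atleast_2d(np.asarray(base_predictions, dtype=float))
    y = np.asarray(responses, dtype=float)
    if not np.isfinite(P).all():
        raise ValueError("non-finite base predictions")
    if np.allclose(P, 0.0):
        raise ValueError("degenerate all-zero base predictions")
    w, _ = _sciopt.nnls(P, y)
    return EnsembleWeights("nnls", w)


def fit_stacking(
    oof_base_predictions: np.ndarray,
    responses: Sequence[float],
    penalty_grid: Sequence[float] = (1e-3, 1e-2, 1e-1, 1.0, 10.0),
) -> EnsembleWeights:
    """Ridge meta-learner on out-of-fold base predictions.

    The penalty is chosen by internal leave-one-out cross-validation
    over ``penalty_grid``.  Feed *out-of-fold* predictions only;
    in-fold predictions leak the training responses into the meta
    level.
    """
    P = np.atleast_2d(np.asarray(oof_base_predictions, dtype=float))
    y = np.asarray(responses, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 rows to fit the meta-learner")
    meta = RidgeCV(alphas=list(penalty_grid))
    meta.fit(P, y)
    return EnsembleWeights("stacking", meta.coef_, float(meta.intercept_))


def fit_average(k: int) -> EnsembleWeights:
    """Equal-weight mean of ``k`` base models."""
    if k < 1:
        raise ValueError("need k >= 1 base models")
    return EnsembleWeights("averaging", np.full(k, 1.0 / k))


def predict_ensemble(
    weights: EnsembleWeights, base_predictions: np.ndarray
) -> np.ndarray:
    """Weighted linear combination (plus intercept for stacking)."""
    P = np.atleast_2d(np.asarray(base_predictions, dtype=float))
    if P.shape[1] != weights.weights.size:
        raise ValueError(
            f"{P.shape[1]} base columns vs {weights.weights.size} weights"
        )
    return P @ weights.weights + weights.intercept


# -- the fitted surrogate used by the optimizer ---------------------------


class Surrogate:
    """All seven tuned base models refit on the full dataset, plus the
    selected family and the three fusions.

    ``predict(X)`` returns the selected model's mean and an uncertainty.
    The uncertainty is the Gaussian-process posterior sd whenever a GP
    family is present in the registry (the default) — it shrinks near
    observed runs and saturates far from them, which keeps the
    upper-confidence search bounded.  Without a GP member the spread
    (sd) across the base-model predictions is used instead; that proxy
    rewards model disagreement, which in strong extrapolation is mostly
    noise, so the GP route is preferred when available.
    """

    def __init__(
        self,
        registry: Sequence[ModelSpec],
        report: CVReport,
        fitted: Mapping[str, object],
        ensembles: Mapping[str, EnsembleWeights],
        ensemble_oof_r2: Mapping[str, float],
    ):
        self.registry = list(registry)
        self.report = report
        self.fitted = dict(fitted)
        self.ensembles = dict(ensembles)
        self.ensemble_oof_r2 = dict(ensemble_oof_r2)
        self.selected_model_id = report.selected_model_id

    def base_predictions(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = []
        for spec in self.registry:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols.append(np.asarray(self.fitted[spec.model_id].predict(X), float))
        return np.column_stack(cols)

    def _gp_member(self) -> GaussianProcessRegressor | None:
        for spec in self.registry:
            model = self.fitted[spec.model_id]
            if isinstance(model, GaussianProcessRegressor):
                return model
        return None

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        model = self.fitted[self.selected_model_id]
        gp = self._gp_member()
        if isinstance(model, GaussianProcessRegressor):
            mean, sd = model.predict(X, return_std=True)
            return np.asarray(mean, float), np.asarray(sd, float)
        if gp is not None:
            _, sd = gp.predict(X, return_std=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mean = np.asarray(model.predict(X), float)
            return mean, np.asarray(sd, float)
        P = self.base_predictions(X)
        j = [s.model_id for s in self.registry].index(self.selected_model_id)
        return P[:, j], P.std(axis=1)

    def predict_fusion(self, method: str, X: np.ndarray) -> np.ndarray:
        return predict_ensemble(self.ensembles[method], self.base_predictions(X))


def fit_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    registry: Sequence[ModelSpec] | None = None,
    outer_folds: int = 9,
    inner_folds: int = 3,
    seed: int = 0,
    report: CVReport | None = None,
) -> Surrogate:
    """Nested-CV evaluation (unless a report is supplied), full-data
    refits with inner-CV-chosen hyperparameters, and the three fusions
    fit on out-of-fold base predictions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    registry = list(registry) if registry is not None else default_registry(seed)
    if report is None:
        report = nested_cv_evaluate(
            X, y, registry, outer_folds=outer_folds,
            inner_folds=inner_folds, seed=seed,
        )
    # full-data refit with hyperparameters chosen on the full data
    fitted: dict[str, object] = {}
    full_params: dict[str, dict] = {}
    for spec in registry:
        params = _inner_search(spec, X, y, inner_folds, seed=seed * 1000 + 999)
        model = clone(spec.estimator)
        model.set_params(**params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        fitted[spec.model_id] = model
        full_params[spec.model_id] = params
    # out-of-fold base predictions for the meta level
    kf = KFold(n_splits=min(outer_folds, len(X)), shuffle=True, random_state=seed)
    oof = np.zeros((len(X), len(registry)))
    for tr, te in kf.split(X):
        for j, spec in enumerate(registry):
            oof[te, j] = _fit_predict(
                spec.estimator, full_params[spec.model_id], X[tr], y[tr], X[te]
            )
    ensembles = {
        "stacking": fit_stacking(oof, y),
        "averaging": fit_average(len(registry)),
        "nnls": fit_nnls(oof, y),
    }
    oof_r2 = {
        m: _r2(y, predict_ensemble(w, oof)) for m, w in ensembles.items()
    }
    return Surrogate(registry, report, fitted, ensembles, oof_r2)
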