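"""Two-level Plackett-Burman screening: design generation, effect
estimation, first-order regression, and significance selection.

A Plackett-Burman design estimates the main effect of up to N-1 factors
in N runs, deliberately ignoring interactions.  Each factor takes a low
(-1) and high (+1) level; the effect of factor i is

    E_i = (sum of responses at +1  -  sum of responses at -1) / N

with N the total number of runs.  With this convention E_i coincides
with the ordinary-least-squares slope of the coded first-order model

    y = beta + sum_i E_i x_i ,

whose intercept beta is the grand mean — the two estimators agree
exactly on any balanced orthogonal design, and the test suite asserts
it.  (The half-difference-of-means reading of the effect is ``2 * E_i``
and is exposed in reports as ``effect_halfdiff``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .factors import FactorSpace, SchemaError

__all__ = [
    "PBDesign",
    "ScreeningResult",
    "generate_pb_design",
    "estimate_effects",
    "fit_first_order",
    "select_significant",
    "predict_first_order",
]

# Published cyclic generating rows (first row of the design; subsequent
# rows are right cyclic shifts; the final run is all minus).
_GENERATORS: dict[int, str] = {
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


class DesignError(ValueError):
    """Unsupported run count, too many factors, or a degenerate matrix."""


@dataclass(frozen=True)
class PBDesign:
    """Coded runs x factors matrix with entries in {-1, +1}."""

    matrix: np.ndarray
    run_order: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.isin(m, (-1.0, 1.0)).all():
            raise DesignError("design entries must be -1 or +1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.matrix.shape[1]

    def is_balanced(self) -> bool:
        return bool((self.matrix.sum(axis=0) == 0).all())

    def is_orthogonal(self) -> bool:
        g = self.matrix.T @ self.matrix
        return bool((g - np.diag(np.diag(g)) == 0).all())


@dataclass
class ScreeningResult:
    """First-order screening fit (coded model).

    ``coefficients`` are the coded-model slopes (mg/L per coded unit),
    identical to the split-sum effects on a balanced orthogonal design.
    ``residual_df = runs - factors - 1``.
    """

    factor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    effects: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    residual_df: int
    alpha: float = 0.05
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.significant is None:
            self.significant = self.p_values < self.alpha
        self.significant = np.asarray(self.significant, dtype=bool)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.factor_names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.factor_names.index(name)])

    def to_records(self) -> list[dict]:
        return [
            {
                "factor": n,
                "coefficient": float(c),
                "effect": float(e),
                "effect_halfdiff": float(2 * e),
                "t_value": float(t),
                "p_value": float(p),
                "significant": bool(s),
            }
            for n, c, e, t, p, s in zip(
                self.factor_names, self.coefficients, self.effects,
                self.t_values, self.p_values, self.significant,
            )
        ]


def generate_pb_design(n_factors: int, n_runs: int) -> PBDesign:
    """Cyclic-generator Plackett-Burman design.

    Supported run counts: 8, 12, 16, 20, 24.  Columns are assigned to
    the first ``n_factors`` positions in factor-space order.  Every
    column is balanced and any two columns are orthogonal; the last run
    sets every factor low.
    """
    if n_runs not in _GENERATORS:
        raise DesignError(
            f"unsupported n_runs={n_runs}; choose from {sorted(_GENERATORS)}"
        )
    if not (1 <= n_factors <= n_runs - 1):
        raise DesignError(
            f"n_factors={n_factors} must be in [1, {n_runs - 1}] for {n_runs} runs"
        )
    row = np.array([1 if c == "+" else -1 for c in _GENERATORS[n_runs]])
    body = np.array([np.roll(row, k) for k in range(n_runs - 1)])
    full = np.vstack([body, -np.ones(n_runs - 1, dtype=int)])
    return PBDesign(full[:, :n_factors].astype(float), tuple(range(1, n_runs + 1)))


def estimate_effects(design: PBDesign, responses: Sequence[float]) -> np.ndarray:
    """Split-sum main effects: (sum at +1 minus sum at -1) / total runs."""
    y = np.asarray(responses, dtype=float)
    if y.shape != (design.n_runs,):
        raise SchemaError(
            f"responses length {y.size} != number of runs {design.n_runs}"
        )
    m = design.matrix
    effects = np.empty(design.n_factors)
    for j in range(design.n_factors):
        plus = y[m[:, j] > 0].sum()
        minus = y[m[:, j] < 0].sum()
        effects[j] = (plus - minus) / design.n_runs
    return effects


def fit_first_order(
    design: PBDesign,
    responses: Sequence[float],
    alpha: float = 0.05,
    factor_names: Sequence[str] | None = None,
) -> ScreeningResult:
    """OLS fit of the coded first-order model with t/p statistics.

    t = coefficient / SE with SE from the residual mean square on
    ``runs - factors - 1`` degrees of freedom; p is two-sided from
    Student's t.  p-values are invariant under affine rescaling of the
    response (the test suite asserts this).
    """
    y = np.asarray(responses, dtype=float)
    n, k = design.n_runs, design.n_factors
    if y.shape != (n,):
        raise SchemaError(f"responses length {y.size} != number of runs {n}")
    if n <= k + 1:
        raise DesignError(f"need runs > factors + 1 (got {n} runs, {k} factors)")
    A = np.hstack([np.ones((n, 1)), design.matrix])
    if np.linalg.matrix_rank(A) < k + 1:
        raise DesignError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    df = n - k - 1
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(s2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    p_all = 2.0 * stats.t.sf(np.abs(t_all), df)
    names = list(factor_names) if factor_names is not None else [
        f"X{j + 1}" for j in range(k)
    ]
    if len(names) != k:
        raise SchemaError("factor_names length does not match design")
    return ScreeningResult(
        factor_names=names,
        intercept=float(coef[0]),
        coefficients=coef[1:],
        effects=estimate_effects(design, y),
        t_values=t_all[1:],
        p_values=p_all[1:],
        residual_df=df,
        alpha=alpha,
    )


def select_significant(result: ScreeningResult, alpha: float | None = None) -> list[str]:
    """Factors with p < alpha, in original factor-space order."""
    a = result.alpha if alpha is None else alpha
    return [
        n for n, p in zip(result.factor_names, result.p_values) if p < a
    ]


def predict_first_order(
    result: ScreeningResult, coded: Sequence[float]
) -> float:
    """Evaluate the fitted first-order model at a coded point."""
    x = np.asarray(coded, dtype=float)
    if x.shape != (result.n_factors,):
        raise SchemaError(
            f"coded vector length {x.size} != factor count {result.n_factors}"
        )
    return float(result.intercept + result.coefficients @ x)
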