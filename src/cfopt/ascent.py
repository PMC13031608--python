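"""Steepest-ascent path construction and evaluation.

After two-level screening, the fitted first-order model points along a
direction of maximal predicted improvement: proportional to the coded
coefficient vector of the chosen factors (positive coefficients step
up, negative step down).  Trials are laid out at equal increments along
that direction and run until the response turns over; the best trial
becomes the center of the next optimization stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .factors import SchemaError
from .screening import ScreeningResult
from .tables import ExperimentTable

__all__ = ["AscentPath", "derive_direction", "generate_path", "best_trial",
           "steps_from_direction"]


class DirectionError(ValueError):
    """All chosen coefficients are zero: the ascent direction is undefined."""


@dataclass
class AscentPath:
    """An affine sequence of trials: trial_i = center + i * step."""

    center: dict[str, float]
    step: dict[str, float]
    n_trials: int
    trials: ExperimentTable


def derive_direction(
    result: ScreeningResult, factors: Sequence[str]
) -> dict[str, float]:
    """Unit direction (coded space) along the coefficient vector
    restricted to ``factors``.

    Component signs equal coefficient signs; zero coefficients give
    zero components.  Raises :class:`DirectionError` when every chosen
    coefficient is zero.
    """
    unknown = [f for f in factors if f not in result.factor_names]
    if unknown:
        raise SchemaError(f"unknown factor(s): {unknown}")
    coef = np.array([result.coefficient(f) for f in factors])
    norm = float(np.linalg.norm(coef))
    if norm == 0.0:
        raise DirectionError("all selected coefficients are zero")
    return {f: float(c / norm) for f, c in zip(factors, coef)}


def steps_from_direction(
    direction: Mapping[str, float],
    base_step: float,
    half_ranges: Mapping[str, float],
    decimals: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Natural-unit steps: ``base_step x direction x half-range``,
    optionally rounded per factor.

    ``base_step`` is the coded-unit length of one trial increment along
    the direction; half-ranges convert each component back to natural
    units.
    """
    steps = {}
    for name, d in direction.items():
        s = base_step * d * half_ranges[name]
        if decimals is not None and name in decimals:
            s = round(s, decimals[name])
        steps[name] = s
    return steps


def generate_path(
    center: Mapping[str, float],
    step: Mapping[str, float],
    n_trials: int,
    rounding: Mapping[str, int] | None = None,
    round_id: int = 0,
) -> AscentPath:
    """Lay out ``n_trials`` equally spaced trials from ``center``.

    Every factor named in ``center`` must have a step entry (use 0.0 to
    hold a factor constant).  Per-factor decimal rounding, when given,
    is applied after the affine formula.
    """
    if n_trials < 1:
        raise SchemaError("n_trials must be >= 1")
    missing = set(center) - set(step)
    if missing:
        raise SchemaError(f"factor(s) missing a step entry: {sorted(missing)}")
    names = list(center)
    runs = []
    for i in range(n_trials):
        settings = {}
        for name in names:
            v = center[name] + i * step[name]
            if rounding is not None and name in rounding:
                v = round(v, rounding[name])
            settings[name] = v
        runs.append(
            {"run_id": f"SA{i + 1}", "round_id": round_id, "settings": settings}
        )
    trials = ExperimentTable.from_runs(runs, names)
    return AscentPath(dict(center), dict(step), n_trials, trials)


def best_trial(path: AscentPath | ExperimentTable) -> tuple[int, float]:
    """Index (0-based) and response of the best answered trial.

    Ties break toward the lowest index.  Raises when no trial has a
    response.
    """
    table = path.trials if isinstance(path, AscentPath) else path
    y = table.responses
    if np.isnan(y).all():
        raise SchemaError("no trial has a recorded response")
    idx = int(np.nanargmax(y))
    return idx, float(y[idx])
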