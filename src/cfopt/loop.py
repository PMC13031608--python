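"""The closed active-learning loop: data in, surrogate training and
selection, batch proposal, experimental validation, repeat until the
yield stabilizes.

Each round trains the model zoo on the cumulative experiment table
(nested CV), refits on all data, proposes a ranked batch of conditions
by upper-confidence search, obtains responses from a *responder* — the
synthetic oracle, or a lab-sheet exchange for real experiments — and
appends them.  The loop stops when the relative improvement of the
best-so-far yield stays at or below a threshold for a configured number
of consecutive rounds, or at ``max_rounds``.

Round state is persisted as JSON so interrupted campaigns resume
exactly: per-round seeds are derived from (base seed, round index) and
the oracle noise stream is counter-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ascent import derive_direction, generate_path, steps_from_direction
from .factors import FactorSpace
from .oracle import Oracle, SCREENING_SPACE
from .screening import fit_first_order, generate_pb_design, select_significant
from .search import CandidateBatch, propose_batch
from .surrogate import ModelSpec, default_registry, fit_surrogate
from .tables import ExperimentTable

__all__ = [
    "LoopConfig",
    "RoundState",
    "run_round",
    "run_loop",
    "check_convergence",
    "oracle_responder",
    "bootstrap_initial_data",
    "save_state",
    "load_state",
]


@dataclass
class LoopConfig:
    """Everything a round needs; defaults follow the workflow's
    published shape (9/3 nested CV, 2000-iteration search, batch 12)."""

    space: FactorSpace
    registry: Sequence[ModelSpec] | None = None
    outer_folds: int = 9
    inner_folds: int = 3
    n_iterations: int = 2000
    batch_size: int = 12
    min_distance: float = 0.05
    kappa: float = 1.0
    threshold: float = 0.02
    patience: int = 2
    max_rounds: int = 10
    n_reps: int = 3
    seed: int = 0

    def round_seed(self, round_index: int) -> int:
        return int((self.seed * 100003 + 17 * round_index + 1) % (2**31))

    def make_registry(self, round_index: int) -> Sequence[ModelSpec]:
        if self.registry is not None:
            return self.registry
        return default_registry(seed=self.round_seed(round_index))


@dataclass
class RoundState:
    """State after ``round_index`` completed rounds."""

    round_index: int
    cumulative: ExperimentTable
    best_settings: dict[str, float]
    best_response: float
    improvement_history: list[float] = field(default_factory=list)
    cv_summary: dict | None = None
    last_batch: CandidateBatch | None = None
    responder_state: dict = field(default_factory=dict)
    audit_log: list[dict] = field(default_factory=list)


def check_convergence(
    history: Sequence[float], threshold: float = 0.02, patience: int = 2
) -> bool:
    """Converged iff the last ``patience`` relative improvements are all
    at or below ``threshold`` (and at least ``patience`` rounds ran)."""
    if len(history) < patience:
        return False
    return all(h <= threshold for h in history[-patience:])


def oracle_responder(oracle: Oracle) -> Callable:
    """Responder closing the loop on the synthetic oracle."""

    def respond(batch: CandidateBatch, round_index: int, n_reps: int):
        out = []
        for c in batch.candidates:
            mean, sd = oracle.query(c.settings, n_reps=n_reps)
            out.append({"settings": c.settings, "response": mean,
                        "replicate_sd": sd, "n_reps": n_reps})
        return out

    respond.get_state = oracle.get_state  # type: ignore[attr-defined]
    respond.set_state = oracle.set_state  # type: ignore[attr-defined]
    return respond


def _best_of(table: ExperimentTable) -> tuple[dict[str, float], float]:
    answered = table.answered()
    y = answered.responses
    i = int(np.argmax(y))
    return answered.settings_of(i), float(y[i])


def initial_state(table: ExperimentTable) -> RoundState:
    settings, best = _best_of(table)
    return RoundState(
        round_index=0,
        cumulative=table,
        best_settings=settings,
        best_response=best,
    )


def run_round(
    state: RoundState,
    config: LoopConfig,
    responder: Callable,
) -> RoundState:
    """Execute one train-propose-validate-append cycle."""
    round_index = state.round_index + 1
    seed = config.round_seed(round_index)
    table = state.cumulative.answered()
    X = table.coded_matrix(config.space)
    y = table.responses
    surrogate = fit_surrogate(
        X, y,
        registry=config.make_registry(round_index),
        outer_folds=min(config.outer_folds, len(y)),
        inner_folds=config.inner_folds,
        seed=seed,
    )
    # anchor the refinement phase at the best conditions measured so far
    top_idx = np.argsort(-y, kind="stable")[:3]
    batch = propose_batch(
        surrogate, config.space,
        n_iterations=config.n_iterations,
        batch_size=config.batch_size,
        min_distance=config.min_distance,
        kappa=config.kappa,
        seed=seed,
        incumbents=X[top_idx],
    )
    answers = responder(batch, round_index, config.n_reps)
    if len(answers) < len(batch.candidates):
        warnings.warn(
            f"round {round_index}: responder answered {len(answers)} of "
            f"{len(batch.candidates)} proposed conditions; proceeding",
            stacklevel=2,
        )
    runs = [
        {
            "run_id": f"R{round_index}C{i + 1}",
            "round_id": round_index,
            "settings": a["settings"],
            "response": a.get("response"),
            "replicate_sd": a.get("replicate_sd"),
            "n_reps": a.get("n_reps", config.n_reps),
        }
        for i, a in enumerate(answers)
    ]
    new_rows = ExperimentTable.from_runs(runs, state.cumulative.factor_names)
    cumulative = state.cumulative.with_rows(new_rows)
    settings, best = _best_of(cumulative)
    prev = state.best_response
    if best < prev:  # monotone best-so-far
        settings, best = state.best_settings, prev
    improvement = (best - prev) / prev if prev > 0 else np.inf
    got = [a.get("response") for a in answers]
    got = [float(v) for v in got if v is not None]
    batch_mean = float(np.mean(got)) if got else float("nan")
    audit_entry = {
        "round": round_index,
        "selected_model": surrogate.selected_model_id,
        "mean_cv_correlation": surrogate.report.mean_correlation(
            surrogate.selected_model_id
        ),
        "ensemble_oof_r2": surrogate.ensemble_oof_r2,
        "batch_mean_response": batch_mean,
        "best_so_far": best,
        "relative_improvement": improvement,
    }
    responder_state = (
        responder.get_state() if hasattr(responder, "get_state") else {}
    )
    return RoundState(
        round_index=round_index,
        cumulative=cumulative,
        best_settings=settings,
        best_response=best,
        improvement_history=state.improvement_history + [improvement],
        cv_summary=surrogate.report.to_dict(),
        last_batch=batch,
        responder_state=responder_state,
        audit_log=state.audit_log + [audit_entry],
    )


def run_loop(
    initial: ExperimentTable | RoundState,
    config: LoopConfig,
    responder: Callable,
    max_rounds: int | None = None,
    outdir: str | Path | None = None,
) -> RoundState:
    """Iterate rounds until convergence or ``max_rounds``.

    Pass a persisted :class:`RoundState` instead of a table to resume
    an interrupted campaign; the result is identical to an
    uninterrupted run with the same seeds.
    """
    state = initial if isinstance(initial, RoundState) else initial_state(initial)
    max_rounds = config.max_rounds if max_rounds is None else max_rounds
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    while state.round_index < max_rounds and not check_convergence(
        state.improvement_history, config.threshold, config.patience
    ):
        state = run_round(state, config, responder)
        if outdir is not None:
            save_state(state, outdir / f"state_{state.round_index}.json")
            if state.last_batch is not None:
                pd.DataFrame(state.last_batch.to_records()).to_csv(
                    outdir / f"batch_{state.round_index}.csv", index=False
                )
    return state


# -- persistence ----------------------------------------------------------


def save_state(state: RoundState, path: str | Path) -> None:
    payload = {
        "round_index": state.round_index,
        "factor_names": state.cumulative.factor_names,
        "cumulative": state.cumulative.data.to_dict(orient="records"),
        "best_settings": state.best_settings,
        "best_response": state.best_response,
        "improvement_history": state.improvement_history,
        "cv_summary": state.cv_summary,
        "responder_state": state.responder_state,
        "audit_log": state.audit_log,
    }
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1))


def load_state(path: str | Path) -> RoundState:
    payload = json.loads(Path(path).read_text())
    df = pd.DataFrame(payload["cumulative"])
    table = ExperimentTable(df, payload["factor_names"])
    return RoundState(
        round_index=int(payload["round_index"]),
        cumulative=table,
        best_settings=payload["best_settings"],
        best_response=float(payload["best_response"]),
        improvement_history=[float(h) for h in payload["improvement_history"]],
        cv_summary=payload.get("cv_summary"),
        responder_state=payload.get("responder_state", {}),
        audit_log=payload.get("audit_log", []),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# -- synthetic-mode initialization ----------------------------------------


def bootstrap_initial_data(
    oracle: Oracle,
    screening_space: FactorSpace = SCREENING_SPACE,
    alpha: float = 0.05,
    n_ascent_trials: int = 5,
    ascent_base_step: float = 2.5,
    n_reps: int = 3,
) -> ExperimentTable:
    """Initial dataset in synthetic mode: a 20-run two-level screening
    design plus a 5-trial steepest-ascent path, both answered by the
    oracle — echoing how the real campaign was initialized.

    The ascent direction comes from the screening fit over the
    significant factors (or the five smallest p-values when fewer than
    two reach significance); one trial increment steps
    ``ascent_base_step`` coded units along the unit direction, i.e.
    roughly ``2.5 / sqrt(k)`` coded units per chosen factor per trial
    for ``k`` chosen factors — the same order as the printed ascent
    path, whose per-trial increments span one to two coded units per
    factor.  Factors outside the path stay at the screening center.
    """
    names = screening_space.names
    design = generate_pb_design(n_factors=len(names), n_runs=20)
    runs = []
    for i in range(design.n_runs):
        coded = design.matrix[i]
        settings = screening_space.to_natural(coded)
        mean, sd = oracle.query(settings, n_reps=n_reps)
        runs.append(
            {"run_id": f"PB{i + 1:02d}", "round_id": 0, "settings": settings,
             "response": mean, "replicate_sd": sd, "n_reps": n_reps}
        )
    pb_table = ExperimentTable.from_runs(runs, names)

    result = fit_first_order(
        design, pb_table.responses, alpha=alpha, factor_names=names
    )
    chosen = select_significant(result)
    if len(chosen) < 2:
        by_p = sorted(names, key=lambda n: result.p_value(n))
        chosen = sorted(by_p[:5], key=names.index)
    direction = derive_direction(result, chosen)
    half = {n: screening_space[n].half_range for n in chosen}
    steps = steps_from_direction(direction, ascent_base_step, half)
    center = {n: screening_space[n].center for n in names}
    full_steps = {n: steps.get(n, 0.0) for n in names}
    path = generate_path(center, full_steps, n_ascent_trials)
    asc_runs = []
    for i in range(n_ascent_trials):
        settings = path.trials.settings_of(i)
        mean, sd = oracle.query(settings, n_reps=n_reps)
        asc_runs.append(
            {"run_id": f"SA{i + 1}", "round_id": 0, "settings": settings,
             "response": mean, "replicate_sd": sd, "n_reps": n_reps}
        )
    asc_table = ExperimentTable.from_runs(asc_runs, names)
    return pb_table.with_rows(asc_table)
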