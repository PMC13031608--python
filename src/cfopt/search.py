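"""Batch proposal by surrogate-guided search with an upper-confidence
acquisition.

The factor space is searched in coded units: a seeded Sobol space
filling covers the first quarter of the evaluation budget, then local
Gaussian perturbations refine around the best scorers found so far.
Every evaluated point is kept; the proposed batch is the top scorers
after a minimum-pairwise-distance filter, so the validated conditions
are distinct rather than near-duplicates of one maximizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .factors import FactorSpace

__all__ = ["Candidate", "CandidateBatch", "acquisition_score", "propose_batch",
           "BatchShortfallError"]


class BatchShortfallError(RuntimeError):
    """Diversity filter left fewer candidates than the requested batch."""


@dataclass(frozen=True)
class Candidate:
    settings: dict[str, float]
    coded: np.ndarray
    predicted_mean: float
    predicted_sd: float
    acquisition: float


@dataclass
class CandidateBatch:
    """Ranked proposals (acquisition descending)."""

    candidates: list[Candidate]
    search_iterations: int
    batch_size: int

    def __len__(self) -> int:
        return len(self.candidates)

    def to_records(self) -> list[dict]:
        return [
            {
                **c.settings,
                "predicted_mean_mg_L": c.predicted_mean,
                "predicted_sd_mg_L": c.predicted_sd,
                "acquisition": c.acquisition,
            }
            for c in self.candidates
        ]


def acquisition_score(
    mean: np.ndarray | float, uncertainty: np.ndarray | float, kappa: float = 1.0
) -> np.ndarray | float:
    """Upper-confidence bound: ``mean + kappa * uncertainty``.

    ``kappa`` trades exploitation (0 = pure predicted mean) against
    exploration of uncertain regions.
    """
    unc = np.asarray(uncertainty, dtype=float)
    if (unc < 0).any():
        raise ValueError("uncertainty must be non-negative")
    return np.asarray(mean, dtype=float) + kappa * unc


def _diverse_top(
    coded: np.ndarray, scores: np.ndarray, batch_size: int, min_distance: float
) -> list[int]:
    """Greedy best-first selection under a pairwise distance floor."""
    order = np.argsort(-scores, kind="stable")
    chosen: list[int] = []
    for i in order:
        if len(chosen) == batch_size:
            break
        if all(
            np.linalg.norm(coded[i] - coded[j]) >= min_distance for j in chosen
        ):
            chosen.append(int(i))
    return chosen


def propose_batch(
    surrogate,
    space: FactorSpace,
    n_iterations: int = 2000,
    batch_size: int = 12,
    min_distance: float = 0.05,
    kappa: float = 1.0,
    seed: int = 0,
    local_sigma: float = 0.15,
    chunk: int = 50,
    incumbents: np.ndarray | None = None,
) -> CandidateBatch:
    """Propose a ranked, diverse validation batch.

    ``surrogate`` must expose ``predict(X) -> (mean, sd)`` over coded
    rows.  The budget of ``n_iterations`` evaluations is spent on a
    seeded Sobol initialization (first quarter) followed by Gaussian
    perturbations (sd ``local_sigma`` in coded units, clipped to
    bounds) around the current top five scorers, re-ranked after each
    chunk.  ``incumbents`` (coded rows, e.g. the best conditions
    measured so far) join the anchor set throughout, so the refinement
    phase always hill-climbs from real observations as well as from
    surrogate optimism.  Identical (seed, surrogate, bounds) give
    identical batches.
    """
    d = len(space)
    rng = np.random.default_rng(seed)
    n_init = max(batch_size, n_iterations // 4)
    n_init = min(n_init, n_iterations)
    sobol = qmc.Sobol(d, scramble=True, rng=np.random.default_rng(seed))
    # draw a power-of-two block (Sobol balance) and keep the first n_init
    pts = sobol.random_base2(int(np.ceil(np.log2(max(n_init, 2)))))[:n_init]
    pts = pts * 2.0 - 1.0  # [0,1]^d -> coded [-1,1]^d
    inc = (
        np.clip(np.atleast_2d(np.asarray(incumbents, dtype=float)), -1.0, 1.0)
        if incumbents is not None and np.size(incumbents)
        else np.empty((0, d))
    )

    all_coded = [pts]
    mean, sd = surrogate.predict(pts)
    all_mean = [np.asarray(mean, float)]
    all_sd = [np.asarray(sd, float)]

    budget = n_iterations - n_init
    while budget > 0:
        size = min(chunk, budget)
        coded_so_far = np.vstack(all_coded)
        scores = acquisition_score(
            np.concatenate(all_mean), np.concatenate(all_sd), kappa
        )
        top = coded_so_far[np.argsort(-scores, kind="stable")[:5]]
        anchor_pool = np.vstack([top, inc]) if len(inc) else top
        anchors = anchor_pool[rng.integers(0, len(anchor_pool), size)]
        prop = np.clip(
            anchors + local_sigma * rng.standard_normal((size, d)), -1.0, 1.0
        )
        m, s = surrogate.predict(prop)
        all_coded.append(prop)
        all_mean.append(np.asarray(m, float))
        all_sd.append(np.asarray(s, float))
        budget -= size

    coded = np.vstack(all_coded)
    mean = np.concatenate(all_mean)
    sd = np.concatenate(all_sd)
    scores = np.asarray(acquisition_score(mean, sd, kappa), dtype=float)

    chosen = _diverse_top(coded, scores, batch_size, min_distance)
    if len(chosen) < batch_size:
        raise BatchShortfallError(
            f"only {len(chosen)} of {batch_size} requested candidates "
            f"survive the min_distance={min_distance} filter"
        )
    cands = [
        Candidate(
            settings=space.to_natural(coded[i]),
            coded=coded[i].copy(),
            predicted_mean=float(mean[i]),
            predicted_sd=float(sd[i]),
            acquisition=float(scores[i]),
        )
        for i in chosen
    ]
    cands.sort(key=lambda c: -c.acquisition)
    return CandidateBatch(cands, n_iterations, batch_size)
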