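"""Synthetic yield landscape: a ground-truth stand-in for the wet lab.

The oracle emulates the qualitative behavior of a multi-enzyme
cell-free biosynthesis reaction over 13 factors (enzyme loadings,
cofactors, substrate, pH, temperature, time, volume):

* a smooth interior optimum with per-factor curvature — yield falls off
  in every direction away from the best condition;
* signed main effects over the two-level screening region that match
  the screening outcome (more PAL enzyme and larger volume help;
  more substrate or CHS enzyme hurt near that region);
* substrate inhibition — yield collapses once the substrate
  concentration passes a threshold (here 6 mM), emulating the observed
  near-total loss of product at high substrate loads;
* pH and temperature optima in the interior of their ranges;
* a few pairwise interactions;
* replicate noise, additive plus multiplicative.

The noiseless landscape is a scaled Gaussian bump

    y(x) = Y_max * exp( z' M z ) * inhibition(x),   z_i = (x_i - opt_i) / s_i

with M negative definite (diagonal = per-factor curvature, off-diagonal
= interactions / 2) and s_i the half-range of the oracle's factor
bounds, so the argmax sits exactly at the configured optimum and yield
is positive everywhere.  This is a test harness shaped by reported
qualitative behavior, not a mechanistic model of the chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .factors import FactorSpace, FactorSpec, SchemaError

__all__ = [
    "InhibitionRule",
    "OracleConfig",
    "Oracle",
    "make_oracle",
    "default_oracle_config",
    "SCREENING_SPACE",
]


class ConfigError(ValueError):
    """Oracle configuration violates its invariants (e.g. convexity)."""


@dataclass(frozen=True)
class InhibitionRule:
    """Yield collapse above a threshold of one factor.

    The noiseless yield is multiplied by ``1 - collapse * s(u)`` where
    ``s`` is a cubic smoothstep ramp over ``[threshold, threshold +
    ramp_width]``.  A ``collapse`` close to 1 means near-total loss.
    """

    factor: str
    threshold: float
    collapse: float
    ramp_width: float = 0.5

    def multiplier(self, value: np.ndarray | float) -> np.ndarray | float:
        u = (np.asarray(value, dtype=float) - self.threshold) / self.ramp_width
        u = np.clip(u, 0.0, 1.0)
        s = 3 * u**2 - 2 * u**3
        return 1.0 - self.collapse * s


@dataclass
class OracleConfig:
    """Ground-truth landscape parameters for the synthetic wet-lab."""

    space: FactorSpace
    optimum: dict[str, float]
    max_yield: float
    curvature: dict[str, float]
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    inhibition: list[InhibitionRule] = field(default_factory=list)
    noise_sd: float = 3.0
    noise_cv: float = 0.05
    n_reps_default: int = 3
    seed: int = 0


#: The 13-factor two-level screening region (low/high screening levels).
SCREENING_SPACE = FactorSpace((
    FactorSpec("ZmPAL", "mg/mL", 1.5, 2.25),
    FactorSpec("At4CL4", "mg/mL", 1.5, 2.25),
    FactorSpec("GmCHS", "mg/mL", 1.25, 1.88),
    FactorSpec("MsCHR", "mg/mL", 1.25, 1.88),
    FactorSpec("ZmCHI", "mg/mL", 1.0, 1.5),
    FactorSpec("CoA", "mM", 1.5, 2.25),
    FactorSpec("ATP", "mM", 1.5, 2.25),
    FactorSpec("NADPH", "mM", 1.5, 2.25),
    FactorSpec("tyrosine", "mM", 2.0, 3.0),
    FactorSpec("pH", "pH", 6.0, 8.0),
    FactorSpec("temperature", "degC", 30.0, 37.0),
    FactorSpec("time", "h", 24.0, 36.0),
    FactorSpec("volume", "uL", 50.0, 75.0),
))

# widened exploration bounds, optimum, curvature (per factor)
_DEFAULT = [
    # name      units    low    high   opt   curv
    ("ZmPAL", "mg/mL", 1.0, 4.5, 4.0, -0.50),
    ("At4CL4", "mg/mL", 0.5, 2.5, 1.2, -0.10),
    ("GmCHS", "mg/mL", 0.25, 2.0, 1.3, -0.50),
    ("MsCHR", "mg/mL", 0.5, 3.5, 3.0, -0.50),
    ("ZmCHI", "mg/mL", 0.5, 2.0, 1.1, -0.10),
    ("CoA", "mM", 0.5, 3.0, 2.5, -0.10),
    ("ATP", "mM", 0.5, 3.0, 2.0, -0.10),
    ("NADPH", "mM", 0.5, 3.0, 1.5, -0.10),
    ("tyrosine", "mM", 0.5, 8.0, 2.0, -0.15),
    ("pH", "pH", 5.0, 9.0, 7.5, -0.50),
    ("temperature", "degC", 16.0, 44.0, 38.0, -0.30),
    ("time", "h", 12.0, 60.0, 28.0, -0.10),
    ("volume", "uL", 25.0, 150.0, 108.0, -0.50),
]


def default_oracle_config(seed: int = 0) -> OracleConfig:
    """The 13-factor default landscape (see module docstring)."""
    space = FactorSpace(
        tuple(FactorSpec(n, u, lo, hi) for n, u, lo, hi, _, _ in _DEFAULT)
    )
    return OracleConfig(
        space=space,
        optimum={n: opt for n, _, _, _, opt, _ in _DEFAULT},
        max_yield=160.0,
        curvature={n: c for n, _, _, _, _, c in _DEFAULT},
        interactions={
            ("ZmPAL", "volume"): 0.08,
            ("GmCHS", "MsCHR"): 0.10,
            ("pH", "temperature"): 0.06,
        },
        inhibition=[InhibitionRule("tyrosine", threshold=6.0, collapse=0.97,
                                   ramp_width=0.5)],
        noise_sd=3.0,
        noise_cv=0.05,
        n_reps_default=3,
        seed=seed,
    )


class Oracle:
    """Callable landscape with a seeded replicate-noise stream.

    The noise stream is counter-based: draw ``k`` uses generator
    ``default_rng([seed, k])``, so persisting the query counter makes
    interrupted runs exactly resumable.
    """

    def __init__(self, config: OracleConfig):
        self.config = config
        space = config.space
        names = space.names
        for name in names:
            if name not in config.optimum:
                raise ConfigError(f"optimum missing factor {name!r}")
            if name not in config.curvature:
                raise ConfigError(f"curvature missing factor {name!r}")
            lo, hi = space[name].low_level, space[name].high_level
            if not (lo < config.optimum[name] < hi):
                raise ConfigError(
                    f"optimum for {name!r} must be interior to its bounds"
                )
        d = len(names)
        M = np.zeros((d, d))
        for i, name in enumerate(names):
            c = config.curvature[name]
            if c >= 0:
                raise ConfigError(
                    f"curvature for {name!r} must be negative (got {c})"
                )
            M[i, i] = c
        for (a, b), v in config.interactions.items():
            i, j = space.index(a), space.index(b)
            M[i, j] += v / 2.0
            M[j, i] += v / 2.0
        eig = np.linalg.eigvalsh(M)
        if eig.max() >= 0:
            raise ConfigError(
                "curvature+interaction matrix must be negative definite "
                f"(max eigenvalue {eig.max():.3g})"
            )
        for rule in config.inhibition:
            if rule.factor not in names:
                raise ConfigError(f"inhibition rule names unknown factor {rule.factor!r}")
            if not (0.0 <= rule.collapse <= 1.0):
                raise ConfigError("collapse fraction must be in [0, 1]")
            if rule.threshold <= config.optimum[rule.factor]:
                raise ConfigError(
                    "inhibition threshold must sit above the optimum "
                    f"for {rule.factor!r}"
                )
        self._M = M
        self._opt = np.array([config.optimum[n] for n in names])
        self._half = np.array([space[n].half_range for n in names])
        self._names = names
        self.n_queries = 0
        self.clip_warnings: list[dict] = []

    # -- landscape --------------------------------------------------------

    def _settings_matrix(self, settings: Mapping[str, float] | Sequence[Mapping[str, float]]) -> np.ndarray:
        if isinstance(settings, Mapping):
            settings = [settings]
        rows = []
        for s in settings:
            missing = set(self._names) - set(s)
            if missing:
                raise SchemaError(f"missing factor setting(s): {sorted(missing)}")
            rows.append([float(s[n]) for n in self._names])
        return np.asarray(rows, dtype=float)

    def noiseless(self, settings) -> np.ndarray:
        """Deterministic yield (mg/L) at one or many settings."""
        X = self._settings_matrix(settings)
        Z = (X - self._opt) / self._half
        expo = np.einsum("ri,ij,rj->r", Z, self._M, Z)
        y = self.config.max_yield * np.exp(expo)
        for rule in self.config.inhibition:
            j = self._names.index(rule.factor)
            y = y * rule.multiplier(X[:, j])
        return y

    def query(
        self,
        settings: Mapping[str, float],
        n_reps: int | None = None,
    ) -> tuple[float, float]:
        """Noisy measurement: mean and sd (mg/L) over ``n_reps`` replicates.

        Settings outside the oracle bounds are clipped to the bounds and
        a warning record is appended to :attr:`clip_warnings`.
        """
        n_reps = self.config.n_reps_default if n_reps is None else int(n_reps)
        if n_reps < 1:
            raise SchemaError("n_reps must be >= 1")
        clipped = dict(settings)
        for name in self._names:
            spec = self.config.space[name]
            v = float(settings[name])
            cv = min(max(v, spec.low_level), spec.high_level)
            if cv != v:
                self.clip_warnings.append(
                    {"factor": name, "requested": v, "clipped_to": cv,
                     "query_index": self.n_queries}
                )
                clipped[name] = cv
        mu = float(self.noiseless(clipped)[0])
        rng = np.random.default_rng([int(self.config.seed), int(self.n_queries)])
        self.n_queries += 1
        draws = mu * (1.0 + self.config.noise_cv * rng.standard_normal(n_reps))
        draws = draws + self.config.noise_sd * rng.standard_normal(n_reps)
        draws = np.clip(draws, 0.0, None)
        sd = float(draws.std(ddof=1)) if n_reps > 1 else 0.0
        return float(draws.mean()), sd

    def true_optimum(self) -> tuple[dict[str, float], float]:
        """Configured optimum settings and the noiseless yield there."""
        settings = {n: float(v) for n, v in zip(self._names, self._opt)}
        return settings, float(self.noiseless(settings)[0])

    # -- resumable state --------------------------------------------------

    def get_state(self) -> dict:
        return {"n_queries": self.n_queries}

    def set_state(self, state: Mapping) -> None:
        self.n_queries = int(state["n_queries"])


def make_oracle(config: OracleConfig | None = None, seed: int | None = None) -> Oracle:
    """Validate a config and return the oracle handle."""
    if config is None:
        config = default_oracle_config(seed=0 if seed is None else seed)
    elif seed is not None:
        config.seed = seed
    return Oracle(config)


def load_oracle_config(path: str | Path) -> OracleConfig:
    """Read an oracle YAML (factors, optimum, curvature, interactions,
    inhibition, noise, seed)."""
    payload = yaml.safe_load(Path(path).read_text())
    space = FactorSpace.from_records(payload["factors"])
    inter = {
        (r["a"], r["b"]): float(r["value"])
        for r in payload.get("interactions", [])
    }
    rules = [
        InhibitionRule(r["factor"], float(r["threshold"]), float(r["collapse"]),
                       float(r.get("ramp_width", 0.5)))
        for r in payload.get("inhibition", [])
    ]
    return OracleConfig(
        space=space,
        optimum={k: float(v) for k, v in payload["optimum"].items()},
        max_yield=float(payload["max_yield"]),
        curvature={k: float(v) for k, v in payload["curvature"].items()},
        interactions=inter,
        inhibition=rules,
        noise_sd=float(payload.get("noise_sd", 3.0)),
        noise_cv=float(payload.get("noise_cv", 0.05)),
        n_reps_default=int(payload.get("n_reps", 3)),
        seed=int(payload.get("seed", 0)),
    )
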