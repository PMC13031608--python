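"""Factor-space definitions and coded/natural unit transforms.

A :class:`FactorSpace` is an ordered collection of experimental factors
(enzyme loadings, cofactor concentrations, pH, temperature, ...), each
with a low and a high level in natural units.  Two-level screening
designs work in *coded* units where the low level maps to -1 and the
high level to +1; all modeling downstream of screening uses the same
coding so that heterogeneous units (mg/mL, mM, uL, degC, h, pH) live on
a common scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = ["FactorSpec", "FactorSpace", "SchemaError"]


class SchemaError(ValueError):
    """Raised when settings or vectors do not match the factor space."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its two-level screening range.

    Parameters
    ----------
    name : str
        Unique identifier within a :class:`FactorSpace`.
    units : str
        Natural units, e.g. ``"mg/mL"``, ``"mM"``, ``"uL"``, ``"degC"``,
        ``"h"``, ``"pH"`` or ``""`` for dimensionless.
    low_level, high_level : float
        The -1 and +1 levels in natural units; ``low_level < high_level``.
    """

    name: str
    units: str
    low_level: float
    high_level: float

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("factor name must be non-empty")
        if not (self.low_level < self.high_level):
            raise SchemaError(
                f"factor {self.name!r}: low_level ({self.low_level}) must be "
                f"strictly below high_level ({self.high_level})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low_level + self.high_level)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high_level - self.low_level)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered, immutable collection of :class:`FactorSpec`.

    Order is significant: design matrices, coded vectors and model
    feature columns all follow it.
    """

    factors: tuple[FactorSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        if len(factors) < 1:
            raise SchemaError("a FactorSpace needs at least one factor")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate factor names: {dupes}")

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    def __getitem__(self, key: int | str) -> FactorSpec:
        if isinstance(key, str):
            for f in self.factors:
                if f.name == key:
                    return f
            raise SchemaError(f"unknown factor name: {key!r}")
        return self.factors[key]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown factor name: {name!r}") from None

    # -- coded <-> natural ------------------------------------------------

    def to_coded(self, settings: Mapping[str, float]) -> np.ndarray:
        """Map natural-unit settings to coded units.

        ``v`` maps to ``2 (v - center) / range`` so the low level is -1
        and the high level +1.  Values outside ``[low, high]`` code to
        values outside ``[-1, +1]`` (extrapolation is allowed: later
        optimization rounds explore beyond the screening region).

        Raises :class:`SchemaError` if any factor is missing from
        ``settings`` or an unknown name is present.
        """
        unknown = set(settings) - set(self.names)
        if unknown:
            raise SchemaError(f"unknown factor name(s): {sorted(unknown)}")
        missing = set(self.names) - set(settings)
        if missing:
            raise SchemaError(f"missing factor setting(s): {sorted(missing)}")
        return np.array(
            [(settings[f.name] - f.center) / f.half_range for f in self.factors],
            dtype=float,
        )

    def to_natural(self, coded: Sequence[float]) -> dict[str, float]:
        """Inverse of :meth:`to_coded`: coded vector to natural-unit map."""
        coded = np.asarray(coded, dtype=float)
        if coded.shape != (len(self),):
            raise SchemaError(
                f"coded vector has length {coded.size}, expected {len(self)}"
            )
        return {
            f.name: f.center + float(c) * f.half_range
            for f, c in zip(self.factors, coded)
        }

    def to_coded_matrix(self, frame) -> np.ndarray:
        """Vectorized coding of a DataFrame with one column per factor."""
        cols = []
        for f in self.factors:
            if f.name not in frame:
                raise SchemaError(f"missing factor column: {f.name!r}")
            v = np.asarray(frame[f.name], dtype=float)
            cols.append((v - f.center) / f.half_range)
        return np.column_stack(cols)

    def clip(self, coded: np.ndarray, low: float = -1.0, high: float = 1.0) -> np.ndarray:
        return np.clip(coded, low, high)

    # -- serialization ----------------------------------------------------

    def to_records(self) -> list[dict]:
        return [
            {"name": f.name, "units": f.units, "low": f.low_level, "high": f.high_level}
            for f in self.factors
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "FactorSpace":
        return cls(
            tuple(
                FactorSpec(
                    name=str(r["name"]),
                    units=str(r.get("units", "")),
                    low_level=float(r["low"]),
                    high_level=float(r["high"]),
                )
                for r in records
            )
        )

    def save(self, path: str | Path) -> None:
        """Write the factor list as JSON or YAML (by extension)."""
        path = Path(path)
        records = self.to_records()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(records, sort_keys=False))
        else:
            path.write_text(json.dumps(records, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FactorSpace":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            records = yaml.safe_load(text)
        else:
            records = json.loads(text)
        return cls.from_records(records)
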