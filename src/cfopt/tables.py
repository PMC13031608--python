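"""Experiment tables: the universal currency between pipeline stages.

An :class:`ExperimentTable` records runs with their factor settings in
natural units, the measured response (product titer in mg/L, possibly
missing for lab sheets awaiting results), the replicate standard
deviation, and the replicate count.  Tables round-trip losslessly
through CSV (comma separator, UTF-8, ``.`` decimal, mandatory header,
empty cell = missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .factors import FactorSpace, SchemaError

__all__ = ["ExperimentTable", "TableParseError", "META_COLUMNS"]

#: non-factor columns, in canonical CSV order (factors go in between)
META_COLUMNS = ("run_id", "round_id", "response_mg_L", "replicate_sd", "n_reps")


class TableParseError(ValueError):
    """Malformed experiment CSV; message names the offending row/column."""


@dataclass
class ExperimentTable:
    """Runs x (settings, response) backed by a pandas DataFrame.

    Columns: ``run_id`` (str), ``round_id`` (int >= 0), one column per
    factor in natural units, ``response_mg_L`` (float, NaN = missing),
    ``replicate_sd`` (float, NaN = missing), ``n_reps`` (int >= 1).
    """

    data: pd.DataFrame
    factor_names: list[str]

    def __post_init__(self) -> None:
        df = self.data
        for col in META_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing column {col!r}")
        for name in self.factor_names:
            if name not in df.columns:
                raise SchemaError(f"missing factor column {name!r}")
        if (df["round_id"] < 0).any():
            raise SchemaError("round_id must be >= 0")
        if (df["n_reps"] < 1).any():
            raise SchemaError("n_reps must be >= 1")
        resp = df["response_mg_L"]
        if (resp.dropna() < 0).any():
            raise SchemaError("responses must be non-negative when present")
        # canonical column order and dtypes
        ordered = ["run_id", "round_id", *self.factor_names,
                   "response_mg_L", "replicate_sd", "n_reps"]
        df = df[ordered].copy()
        df["run_id"] = df["run_id"].astype(str)
        df["round_id"] = df["round_id"].astype(int)
        df["n_reps"] = df["n_reps"].astype(int)
        for c in (*self.factor_names, "response_mg_L", "replicate_sd"):
            df[c] = df[c].astype(float)
        self.data = df.reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_runs(
        cls,
        runs: Sequence[Mapping],
        factor_names: Sequence[str],
    ) -> "ExperimentTable":
        """Build from dicts with keys run_id, round_id, settings (map),
        response, replicate_sd, n_reps (the last three optional)."""
        records = []
        for r in runs:
            rec = {
                "run_id": r["run_id"],
                "round_id": r.get("round_id", 0),
                "response_mg_L": r.get("response", np.nan),
                "replicate_sd": r.get("replicate_sd", np.nan),
                "n_reps": r.get("n_reps", 1),
            }
            settings = r["settings"]
            for name in factor_names:
                if name not in settings:
                    raise SchemaError(
                        f"run {r['run_id']!r}: missing setting {name!r}"
                    )
                rec[name] = settings[name]
            records.append(rec)
        return cls(pd.DataFrame(records), list(factor_names))

    def bind(self, space: FactorSpace) -> "ExperimentTable":
        """Validate that every factor column exists in ``space``."""
        unknown = set(self.factor_names) - set(space.names)
        if unknown:
            raise SchemaError(f"factor column(s) not in space: {sorted(unknown)}")
        return self

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def responses(self) -> np.ndarray:
        return self.data["response_mg_L"].to_numpy()

    def settings_of(self, i: int) -> dict[str, float]:
        row = self.data.iloc[i]
        return {name: float(row[name]) for name in self.factor_names}

    def coded_matrix(self, space: FactorSpace) -> np.ndarray:
        """Feature matrix in coded units (see :meth:`FactorSpace.to_coded`)."""
        self.bind(space)
        return space.to_coded_matrix(self.data)

    def with_rows(self, other: "ExperimentTable") -> "ExperimentTable":
        if other.factor_names != self.factor_names:
            raise SchemaError("factor columns differ between tables")
        df = pd.concat([self.data, other.data], ignore_index=True)
        return ExperimentTable(df, list(self.factor_names))

    def answered(self) -> "ExperimentTable":
        """Rows whose response is present."""
        df = self.data[self.data["response_mg_L"].notna()]
        return ExperimentTable(df.copy(), list(self.factor_names))

    def equals(self, other: "ExperimentTable") -> bool:
        return (
            self.factor_names == other.factor_names
            and self.data.equals(other.data)
        )

    # -- CSV I/O ----------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path) -> "ExperimentTable":
        """Read from a path or an open text buffer."""
        if isinstance(path, (str, Path)):
            path = Path(path)
        try:
            raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        except Exception as exc:  # header / IO problems
            raise TableParseError(f"{path}: {exc}") from exc
        missing = [c for c in META_COLUMNS if c not in raw.columns]
        if missing:
            raise TableParseError(f"{path}: missing column(s) {missing}")
        factor_names = [c for c in raw.columns if c not in META_COLUMNS]

        def parse(col: str, required: bool) -> pd.Series:
            out = []
            for i, cell in enumerate(raw[col]):
                cell = cell.strip()
                if cell == "":
                    if required:
                        raise TableParseError(
                            f"{path}: empty required cell at row {i + 1}, "
                            f"column {col!r}"
                        )
                    out.append(np.nan)
                    continue
                try:
                    out.append(float(cell))
                except ValueError:
                    raise TableParseError(
                        f"{path}: malformed numeric cell {cell!r} at "
                        f"row {i + 1}, column {col!r}"
                    ) from None
            return pd.Series(out, dtype=float)

        df = pd.DataFrame({"run_id": raw["run_id"]})
        df["round_id"] = parse("round_id", required=True).astype(int)
        for name in factor_names:
            df[name] = parse(name, required=True)
        df["response_mg_L"] = parse("response_mg_L", required=False)
        df["replicate_sd"] = parse("replicate_sd", required=False)
        n_reps = parse("n_reps", required=False)
        df["n_reps"] = n_reps.fillna(1).astype(int)
        return cls(df, factor_names)


def read_table(path: str | Path) -> ExperimentTable:
    """Read an experiment CSV (see module docstring for the dialect)."""
    return ExperimentTable.read_csv(path)


def write_table(table: ExperimentTable, path: str | Path) -> None:
    """Write an experiment CSV; missing responses become empty cells."""
    table.write_csv(path)
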