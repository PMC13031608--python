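"""Packaged reference data: the 13-factor screening table, the 20-run
two-level design with measured liquiritigenin titers, the 5-trial
steepest-ascent path, and a small ledger of headline yields.

These are read-only transcriptions of printed experiment tables.  The
screening statistics shipped with the factor table (coefficient, t, p)
are the *printed* values; ``cfopt.screening.fit_first_order`` recomputes
them from the 20-run table, and the recomputed p-values agree with the
printed ones to printed precision while the printed coefficients differ
from the recomputed ones by a single global response-scaling factor
(see docs/methods.md).  Files are checksummed so fixture drift fails
loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .factors import FactorSpace, FactorSpec
from .screening import ScreeningResult
from .tables import ExperimentTable

__all__ = ["PrintedLedger", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("pb_factors", "pb_runs", "ascent_trials", "ledger", "pb_screening")

_CHECKSUMS = {
    "pb_factors.json": "d32dfab0cb34873f6d68f221bba125a2337678847fb7b7f2ed0bc05a3e33a4e2",
    "pb_runs.csv": "0bdf18c8447e7ece8ec6db4c7a8532bfcdd55508cb5255a97eccdf1250e774b4",
    "ascent_trials.csv": "f9c8139a8b572b49e1f4df6e08b712c9f816d56234b5ce1981ecbb4247e4c449",
    "ledger.json": "39fd1809f17efaa0c9fa43773937ee83f831a1e7c44dfc03d72facf8080273fa",
}


@dataclass(frozen=True)
class PrintedLedger:
    """Named headline yields (mg/L) kept as read-only constants.

    These are wet-lab measurements; nothing in the package recomputes
    them.  They exist for worked-example arithmetic (fold changes,
    percentage improvements).
    """

    constants: dict

    def value(self, name: str) -> float:
        return float(self.constants[name]["value"])

    def names(self) -> list[str]:
        return list(self.constants)

    def __len__(self) -> int:
        return len(self.constants)


def _read_bytes(filename: str) -> bytes:
    blob = (resources.files("cfopt") / "data" / filename).read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    expected = _CHECKSUMS[filename]
    if digest != expected:
        raise RuntimeError(
            f"fixture {filename} checksum mismatch: {digest} != {expected}"
        )
    return blob


def _factor_payload() -> dict:
    return json.loads(_read_bytes("pb_factors.json"))


def _load_table(filename: str) -> ExperimentTable:
    import io

    blob = _read_bytes(filename)
    return ExperimentTable.read_csv(io.StringIO(blob.decode("utf-8")))


def load_fixture(name: str):
    """Return a packaged fixture by name.

    ============== ==============================================
    name           returns
    ============== ==============================================
    pb_factors     :class:`FactorSpace` (13 factors, screening levels)
    pb_runs        :class:`ExperimentTable` (20 runs, natural units)
    ascent_trials  :class:`ExperimentTable` (5 trials, 5 factors)
    ledger         :class:`PrintedLedger` (4 headline yields)
    pb_screening   :class:`ScreeningResult` (printed coefficients/t/p)
    ============== ==============================================
    """
    if name == "pb_factors":
        payload = _factor_payload()
        return FactorSpace(
            tuple(
                FactorSpec(r["name"], r["units"], r["low"], r["high"])
                for r in payload["factors"]
            )
        )
    if name == "pb_screening":
        payload = _factor_payload()
        recs = payload["factors"]
        return ScreeningResult(
            factor_names=[r["name"] for r in recs],
            intercept=float(payload["intercept"]),
            coefficients=np.array([r["printed"]["coefficient"] for r in recs]),
            effects=np.array([r["printed"]["coefficient"] for r in recs]),
            t_values=np.array([r["printed"]["t_value"] for r in recs]),
            p_values=np.array([r["printed"]["p_value"] for r in recs]),
            residual_df=20 - 13 - 1,
            alpha=float(payload["alpha"]),
        )
    if name == "pb_runs":
        return _load_table("pb_runs.csv")
    if name == "ascent_trials":
        return _load_table("ascent_trials.csv")
    if name == "ledger":
        return PrintedLedger(json.loads(_read_bytes("ledger.json")))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
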