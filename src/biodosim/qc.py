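"""Radiopharmaceutical production QC: batch summaries and release criteria.

A validation campaign consists of a handful of production runs, each with a
panel of release parameters — some numeric (activity yield, molar activity,
radiochemical purity, residual solvents, pH, measured half-life), some
qualitative (appearance, sterility, filter integrity), and some reported only
as "below the limit of quantification".  This module aggregates numeric
parameters across runs, estimates the radionuclide half-life from paired
dose-calibrator readings, and evaluates each run against inclusive-bound
acceptance criteria.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biodist import ValidationError

__all__ = [
    "QCRun",
    "Criterion",
    "ReleaseCriteria",
    "LOQValue",
    "batch_summary",
    "estimate_half_life",
    "evaluate_release",
    "read_qc_runs_csv",
    "load_criteria",
]


@dataclass(frozen=True)
class LOQValue:
    """A measurement reported only as below a limit of quantification."""

    loq: float

    def __str__(self) -> str:  # round-trips the CSV encoding
        return f"<LOQ:{self.loq:g}"


Measurement = float | str | LOQValue


@dataclass(frozen=True)
class QCRun:
    """One production run's QC panel: parameter -> value.

    Values are numeric, qualitative (``"pass"``/``"fail"``), or
    :class:`LOQValue` for below-quantification results.
    """

    run_id: str
    measurements: Mapping[str, Measurement]
    units: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Criterion:
    """Acceptance window for one parameter; bounds are inclusive."""

    min: float | None = None
    max: float | None = None
    qualitative_expected: str | None = None

    def __post_init__(self) -> None:
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValidationError(f"criterion min {self.min} > max {self.max}")


@dataclass(frozen=True)
class ReleaseCriteria:
    name: str
    criteria: Mapping[str, Criterion]


def batch_summary(
    runs: Sequence[QCRun], parameter: str
) -> tuple[float, float | None, int]:
    """Sample mean and SD (n-1) of a numeric parameter across runs.

    Values are aggregated at full precision; rounding (3 significant figures
    by convention) is left to formatting.  SD is None for a single run.
    """
    values = []
    for run in runs:
        if parameter not in run.measurements:
            raise ValidationError(f"run {run.run_id!r} lacks parameter {parameter!r}")
        v = run.measurements[parameter]
        if not isinstance(v, (int, float)):
            raise ValidationError(
                f"parameter {parameter!r} is not numeric in run {run.run_id!r}: {v!r}"
            )
        values.append(float(v))
    arr = np.asarray(values)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else None
    return float(np.mean(arr)), sd, len(arr)


def estimate_half_life(
    a1: float, a2: float, t2_min: float, t1_min: float = 0.0
) -> float:
    """Half-life (minutes) from two activity readings: t1/2 = ln2 (t2-t1)/ln(a1/a2)."""
    if not (a1 > a2 > 0):
        raise ValidationError("requires decreasing positive activities a1 > a2 > 0")
    if not t2_min > t1_min:
        raise ValidationError("requires t2 > t1")
    return math.log(2.0) * (t2_min - t1_min) / math.log(a1 / a2)


def _check_one(value: Measurement, crit: Criterion) -> tuple[bool, str]:
    if crit.qualitative_expected is not None:
        ok = str(value).strip().lower() == crit.qualitative_expected.strip().lower()
        return ok, f"qualitative: {value!r} vs expected {crit.qualitative_expected!r}"
    if isinstance(value, LOQValue):
        # below-LOQ passes a max bound that admits the LOQ itself; a min bound
        # cannot be demonstrated from a below-LOQ reading
        if crit.min is not None:
            return False, f"below LOQ {value.loq:g} cannot satisfy min bound {crit.min:g}"
        if crit.max is not None:
            ok = crit.max >= value.loq
            return ok, f"<LOQ:{value.loq:g} vs max {crit.max:g}"
        return True, "no bounds"
    if not isinstance(value, (int, float)):
        return False, f"non-numeric value {value!r} for a numeric criterion"
    v = float(value)
    if crit.min is not None and v < crit.min:
        return False, f"{v:g} < min {crit.min:g}"
    if crit.max is not None and v > crit.max:
        return False, f"{v:g} > max {crit.max:g}"
    return True, f"{v:g} within bounds"


def evaluate_release(
    run: QCRun, criteria: ReleaseCriteria
) -> tuple[dict[str, tuple[bool, str]], bool]:
    """Check one run against release criteria.

    Returns per-parameter (pass, detail) plus the overall verdict, which is
    the conjunction of the per-parameter results.  Bounds are inclusive.
    """
    results: dict[str, tuple[bool, str]] = {}
    for parameter, crit in criteria.criteria.items():
        if parameter not in run.measurements:
            raise ValidationError(
                f"run {run.run_id!r} is missing parameter {parameter!r} required "
                f"by criteria {criteria.name!r}"
            )
        results[parameter] = _check_one(run.measurements[parameter], crit)
    overall = all(ok for ok, _ in results.values())
    return results, overall


def _parse_measurement(raw: object) -> Measurement:
    s = str(raw).strip()
    if s.lower().startswith("<loq:"):
        return LOQValue(loq=float(s[5:]))
    try:
        return float(s)
    except ValueError:
        return s


def read_qc_runs_csv(path: str | Path) -> list[QCRun]:
    """Read QC runs: one row per run, first column ``run_id``, one column
    per parameter."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "run_id":
        raise ValidationError("QC runs CSV must have 'run_id' as its first column")
    runs = []
    for _, row in df.iterrows():
        measurements = {
            col: _parse_measurement(row[col]) for col in df.columns[1:] if pd.notna(row[col])
        }
        runs.append(QCRun(run_id=str(row["run_id"]), measurements=measurements))
    return runs


def load_criteria(path: str | Path) -> ReleaseCriteria:
    """Read release criteria JSON:
    ``{name, criteria: {param: {min?, max?, qualitative_expected?}}}``."""
    with open(path) as fh:
        d = json.load(fh)
    crits = {
        k: Criterion(
            min=v.get("min"), max=v.get("max"),
            qualitative_expected=v.get("qualitative_expected"),
        )
        for k, v in d["criteria"].items()
    }
    return ReleaseCriteria(name=d.get("name", Path(path).stem), criteria=crits)
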