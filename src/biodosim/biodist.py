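"""Biodistribution data model and I/O.

A gamma-counter biodistribution study yields, for each euthanised animal and
harvested organ, a tissue mass and a radioactivity reading.  The standard
presentation is percent injected dose per gram of tissue (%ID/g),
decay-corrected back to injection time.  This module holds the record types,
converts raw counts to %ID/g, applies physical decay in either direction, and
computes per-group summary statistics (mean +/- SD over the n animals in each
sex x time-point x blocked cell).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Isotope",
    "TissueSample",
    "BiodistRecord",
    "GroupSummary",
    "FLUORINE_18",
    "ValidationError",
    "compute_pct_id_g",
    "apply_physical_decay",
    "summarize_groups",
    "read_biodist_csv",
    "write_biodist_csv",
    "records_to_frame",
    "frame_to_records",
    "load_isotope",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Isotope:
    """A positron- or gamma-emitting radionuclide.

    Parameters
    ----------
    name:
        Nuclide label, e.g. ``"F-18"``.
    half_life_min:
        Physical half-life in minutes; must be positive.
    mean_np_energy_mev:
        Mean non-penetrating (beta/positron) energy per decay in MeV.  Only
        the sphere self-dose fallback consumes this.
    beta_branching:
        Fraction of decays emitting the non-penetrating particle.
    """

    name: str
    half_life_min: float
    mean_np_energy_mev: float = 0.0
    beta_branching: float = 1.0

    def __post_init__(self) -> None:
        if not (self.half_life_min > 0 and math.isfinite(self.half_life_min)):
            raise ValidationError(f"half_life_min must be > 0, got {self.half_life_min}")
        if self.mean_np_energy_mev < 0:
            raise ValidationError("mean_np_energy_mev must be >= 0")
        if not 0 <= self.beta_branching <= 1:
            raise ValidationError("beta_branching must be in [0, 1]")

    @property
    def half_life_h(self) -> float:
        return self.half_life_min / 60.0

    @property
    def lambda_phys_per_h(self) -> float:
        """Physical decay constant in 1/h."""
        return math.log(2.0) / self.half_life_h

    @property
    def delta_np_mev(self) -> float:
        """Mean non-penetrating energy emitted per decay (MeV), branching included."""
        return self.mean_np_energy_mev * self.beta_branching


# Fluorine-18: T1/2 = 109.77 min; mean positron energy 0.2498 MeV/decay at a
# branching ratio of 0.9686.  Overridable via an isotope JSON file.
FLUORINE_18 = Isotope(
    name="F-18",
    half_life_min=109.77,
    mean_np_energy_mev=0.2498,
    beta_branching=0.9686,
)


@dataclass(frozen=True)
class TissueSample:
    """One raw gamma-counter measurement, referenced to injection time."""

    animal_id: str
    organ: str
    sample_mass_g: float
    net_counts: float
    count_time_h: float
    injected_counts: float

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ValidationError(f"sample_mass_g must be > 0, got {self.sample_mass_g}")
        if self.injected_counts <= 0:
            raise ValidationError(f"injected_counts must be > 0, got {self.injected_counts}")
        if self.net_counts < 0:
            raise ValidationError(f"net_counts must be >= 0, got {self.net_counts}")
        if self.count_time_h < 0:
            raise ValidationError(f"count_time_h must be >= 0, got {self.count_time_h}")


@dataclass(frozen=True)
class BiodistRecord:
    """One tissue uptake value in %ID/g with study metadata.

    ``pct_id_g`` is stored decay-corrected to injection time (the conventional
    biodistribution presentation); downstream dosimetry re-applies physical
    decay explicitly before curve fitting.
    """

    animal_id: str
    sex: Literal["F", "M"]
    timepoint_h: float
    blocked: bool
    organ: str
    pct_id_g: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.timepoint_h <= 0:
            raise ValidationError(f"timepoint_h must be > 0, got {self.timepoint_h}")
        if self.pct_id_g < 0:
            raise ValidationError(f"pct_id_g must be >= 0, got {self.pct_id_g}")


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD of %ID/g over one (sex, organ, timepoint, blocked) cell."""

    sex: str
    organ: str
    timepoint_h: float
    blocked: bool
    n: int
    mean: float
    sd: float | None  # None (undefined) when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be >= 0 when defined")


def compute_pct_id_g(
    sample: TissueSample,
    isotope: Isotope,
    decay_correct: bool = True,
    *,
    sex: str = "F",
    timepoint_h: float | None = None,
    blocked: bool = False,
) -> BiodistRecord:
    """Convert a raw counts measurement to a %ID/g record.

    %ID/g = 100 x (net_counts x decay_factor) / injected_counts / mass, where
    the decay factor exp(+lambda_phys * t) refers the counts measured at
    ``count_time_h`` back to injection time (``decay_correct=True``), and the
    injected-dose standard is already referenced to injection time.
    """
    factor = (
        math.exp(isotope.lambda_phys_per_h * sample.count_time_h) if decay_correct else 1.0
    )
    pct = 100.0 * sample.net_counts * factor / sample.injected_counts / sample.sample_mass_g
    t = sample.count_time_h if timepoint_h is None else timepoint_h
    return BiodistRecord(
        animal_id=sample.animal_id,
        sex=sex,  # type: ignore[arg-type]
        timepoint_h=t,
        blocked=blocked,
        organ=sample.organ,
        pct_id_g=pct,
    )


def apply_physical_decay(
    value: float | np.ndarray,
    t_h: float | np.ndarray,
    isotope: Isotope,
    direction: Literal["decay", "correct"] = "decay",
) -> float | np.ndarray:
    """Apply physical decay over ``t_h`` hours, or undo it.

    ``direction="decay"`` multiplies by exp(-lambda t) (injection -> time point);
    ``direction="correct"`` multiplies by exp(+lambda t).  The round trip is the
    identity.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t_h must be >= 0")
    if direction not in ("decay", "correct"):
        raise ValidationError(f"direction must be 'decay' or 'correct', got {direction!r}")
    sign = -1.0 if direction == "decay" else 1.0
    out = np.asarray(value, dtype=float) * np.exp(sign * isotope.lambda_phys_per_h * t)
    if np.isscalar(value) or (isinstance(value, float) and out.ndim == 0):
        return float(out)
    return out if out.ndim else float(out)


def records_to_frame(records: Iterable[BiodistRecord]) -> pd.DataFrame:
    """Tabulate records; columns match the pctid CSV dialect."""
    rows = [
        (r.animal_id, r.sex, r.timepoint_h, int(r.blocked), r.organ, r.pct_id_g)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["animal_id", "sex", "timepoint_h", "blocked", "organ", "pct_id_g"]
    )


def frame_to_records(df: pd.DataFrame) -> list[BiodistRecord]:
    return [
        BiodistRecord(
            animal_id=str(row.animal_id),
            sex=str(row.sex),  # type: ignore[arg-type]
            timepoint_h=float(row.timepoint_h),
            blocked=bool(int(row.blocked)),
            organ=str(row.organ),
            pct_id_g=float(row.pct_id_g),
        )
        for row in df.itertuples(index=False)
    ]


_PCTID_COLS = ["animal_id", "sex", "timepoint_h", "blocked", "organ", "sample_mass_g", "pct_id_g"]
_RAW_COLS = [
    "animal_id", "sex", "timepoint_h", "blocked", "organ",
    "sample_mass_g", "net_counts", "count_time_h", "injected_counts",
]


def read_biodist_csv(
    path: str | Path,
    isotope: Isotope = FLUORINE_18,
    decay_correct_raw: bool = True,
) -> list[BiodistRecord]:
    """Read a biodistribution CSV in either the pctid or the raw-counts dialect.

    The dialect is declared by the header: a ``pct_id_g`` column selects the
    pctid dialect, a ``net_counts`` column the raw dialect; it is never guessed
    from the values.  Raw counts are converted with :func:`compute_pct_id_g`,
    decay-correcting to injection time by default.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if "pct_id_g" in cols:
        missing = [c for c in _PCTID_COLS if c not in cols and c != "sample_mass_g"]
        if missing:
            raise ValidationError(f"pctid dialect missing columns: {missing}")
        return frame_to_records(df)
    if "net_counts" in cols:
        missing = [c for c in _RAW_COLS if c not in cols]
        if missing:
            raise ValidationError(f"raw dialect missing columns: {missing}")
        records = []
        for row in df.itertuples(index=False):
            sample = TissueSample(
                animal_id=str(row.animal_id),
                organ=str(row.organ),
                sample_mass_g=float(row.sample_mass_g),
                net_counts=float(row.net_counts),
                count_time_h=float(row.count_time_h),
                injected_counts=float(row.injected_counts),
            )
            records.append(
                compute_pct_id_g(
                    sample,
                    isotope,
                    decay_correct=decay_correct_raw,
                    sex=str(row.sex),
                    timepoint_h=float(row.timepoint_h),
                    blocked=bool(int(row.blocked)),
                )
            )
        return records
    raise ValidationError(
        "unrecognised biodistribution CSV dialect: need a 'pct_id_g' or 'net_counts' column"
    )


def write_biodist_csv(records: Sequence[BiodistRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def summarize_groups(records: Sequence[BiodistRecord]) -> list[GroupSummary]:
    """Per-group sample mean and SD (n-1 denominator); SD undefined for n=1."""
    if not records:
        raise ValidationError("summarize_groups requires a non-empty record table")
    df = records_to_frame(records)
    out: list[GroupSummary] = []
    for (sex, organ, t, blocked), grp in df.groupby(
        ["sex", "organ", "timepoint_h", "blocked"], sort=True
    ):
        vals = grp["pct_id_g"].to_numpy()
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else None
        out.append(
            GroupSummary(
                sex=str(sex),
                organ=str(organ),
                timepoint_h=float(t),
                blocked=bool(blocked),
                n=n,
                mean=float(np.mean(vals)),
                sd=sd,
            )
        )
    return out


def load_isotope(path: str | Path) -> Isotope:
    """Load an isotope description from JSON
    (``{name, half_life_min, mean_np_energy_mev, beta_branching}``)."""
    with open(path) as fh:
        d = json.load(fh)
    return Isotope(
        name=d["name"],
        half_life_min=float(d["half_life_min"]),
        mean_np_energy_mev=float(d.get("mean_np_energy_mev", 0.0)),
        beta_branching=float(d.get("beta_branching", 1.0)),
    )
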