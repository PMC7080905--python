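"""Time-integrated activity coefficients (residence times).

The time-integrated activity coefficient tau of a source organ is the total
number of decays occurring in it per unit administered activity, in hours.
Integrating a fitted %ID/g curve over [0, inf) gives an area in %ID*h/g; the
coefficient follows by multiplying with the organ mass of the dosimetric
phantom and dividing by 100.  For cross-species extrapolation the
concentration can additionally be rescaled by the ratio of whole-body masses
(relative mass scaling), the common practice when projecting rodent
concentration data onto a human phantom.

Activity not assigned to an explicit organ is booked under "remainder of
body" so that the source set handed to the dose engine is complete: for a
non-excreting subject, total time-integrated activity cannot exceed
T1/2 / ln 2 hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .biodist import Isotope, ValidationError
from .kinetics import KineticFit

__all__ = [
    "Phantom",
    "TIACTable",
    "REMAINDER",
    "integrate_model",
    "organ_tiac",
    "remainder_tiac",
    "load_phantom",
    "write_tiac_csv",
    "read_tiac_csv",
]

#: reserved organ label for the remainder-of-body row
REMAINDER = "remainder"


@dataclass(frozen=True)
class Phantom:
    """A dosimetric anatomical model: whole-body mass and organ masses (g)."""

    name: str
    body_mass_g: float
    organ_masses: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.body_mass_g <= 0:
            raise ValidationError("body_mass_g must be > 0")
        for organ, m in self.organ_masses.items():
            if m <= 0:
                raise ValidationError(f"organ mass must be > 0: {organ} = {m}")
        total = sum(self.organ_masses.values())
        if total > self.body_mass_g * (1 + 1e-9):
            raise ValidationError(
                f"organ masses sum to {total:.1f} g > body mass {self.body_mass_g:.1f} g"
            )

    def mass(self, organ: str) -> float:
        try:
            return self.organ_masses[organ]
        except KeyError:
            raise KeyError(
                f"organ {organ!r} not in phantom {self.name!r}; "
                f"available: {sorted(self.organ_masses)}"
            ) from None

    @property
    def remainder_mass_g(self) -> float:
        return self.body_mass_g - sum(self.organ_masses.values())


@dataclass(frozen=True)
class TIACTable:
    """Per-source-organ time-integrated activity coefficients (hours)."""

    phantom: Phantom
    entries: Mapping[str, float]
    remainder_h: float
    cap_h: float | None = None

    def __post_init__(self) -> None:
        for organ, tau in self.entries.items():
            if tau < 0:
                raise ValidationError(f"tau must be >= 0: {organ} = {tau}")
        if self.remainder_h < 0:
            raise ValidationError("remainder_h must be >= 0")
        if self.cap_h is not None:
            total = sum(self.entries.values()) + self.remainder_h
            if total > self.cap_h + 1e-9:
                raise ValidationError(
                    f"total TIAC {total:.6f} h exceeds cap {self.cap_h:.6f} h"
                )

    @property
    def total_h(self) -> float:
        return sum(self.entries.values()) + self.remainder_h


def integrate_model(fit: KineticFit) -> float:
    """Area under the fitted curve on [0, inf): sum_i A_i / lambda_i (%ID*h/g)."""
    if any(l <= 0 for l in fit.rates):
        raise ValidationError("all rates must be > 0 for a finite integral")
    return sum(a / l for a, l in zip(fit.amplitudes, fit.rates))


def organ_tiac(
    area: float,
    organ: str,
    source_phantom: Phantom,
    target_phantom: Phantom,
    strategy: Literal["direct", "relative_body_mass"] = "relative_body_mass",
) -> float:
    """Convert a TAC area (%ID*h/g) into the target phantom's organ coefficient.

    ``direct``:             tau = area * m_organ(target) / 100
    ``relative_body_mass``: tau = area * (M_body(source)/M_body(target))
                                  * m_organ(target) / 100

    The two strategies coincide when source and target are the same phantom.
    """
    if area < 0:
        raise ValidationError("area must be >= 0")
    if strategy not in ("direct", "relative_body_mass"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    m = target_phantom.mass(organ)
    scale = 1.0
    if strategy == "relative_body_mass":
        scale = source_phantom.body_mass_g / target_phantom.body_mass_g
    return area * scale * m / 100.0


def remainder_tiac(
    entries: Mapping[str, float],
    isotope: Isotope,
    whole_body_tau: float | None = None,
) -> float:
    """Remainder-of-body coefficient: whole-body total minus the organ sum.

    Without a fitted whole-body curve the total defaults to the no-excretion
    physical maximum T1/2 / ln 2 (hours).  A deficit beyond 1e-9 h — organ
    coefficients exceeding the whole-body total — is a consistency error.
    """
    if any(tau < 0 for tau in entries.values()):
        raise ValidationError("all tau entries must be >= 0")
    cap = whole_body_tau if whole_body_tau is not None else isotope.half_life_h / math.log(2.0)
    total = sum(entries.values())
    remainder = cap - total
    if remainder < -1e-9:
        raise ValidationError(
            f"organ TIACs sum to {total:.6f} h, exceeding the whole-body cap "
            f"{cap:.6f} h by {-remainder:.3g} h"
        )
    return max(remainder, 0.0)


def build_tiac_table(
    areas: Mapping[str, float],
    source_phantom: Phantom,
    target_phantom: Phantom,
    isotope: Isotope,
    strategy: Literal["direct", "relative_body_mass"] = "relative_body_mass",
    whole_body_tau: float | None = None,
) -> TIACTable:
    """Assemble a complete TIAC table (organs + remainder) from TAC areas."""
    entries = {
        organ: organ_tiac(area, organ, source_phantom, target_phantom, strategy)
        for organ, area in areas.items()
    }
    cap = whole_body_tau if whole_body_tau is not None else isotope.half_life_h / math.log(2.0)
    rem = remainder_tiac(entries, isotope, whole_body_tau)
    return TIACTable(phantom=target_phantom, entries=entries, remainder_h=rem, cap_h=cap)


def load_phantom(path: str | Path) -> Phantom:
    """Load a phantom from JSON (``{name, body_mass_g, organs: {organ: g}}``)."""
    with open(path) as fh:
        d = json.load(fh)
    return Phantom(
        name=d["name"],
        body_mass_g=float(d["body_mass_g"]),
        organ_masses={k: float(v) for k, v in d["organs"].items()},
    )


def write_tiac_csv(table: TIACTable, path: str | Path) -> None:
    rows = [(organ, tau) for organ, tau in sorted(table.entries.items())]
    rows.append(("REMAINDER", table.remainder_h))
    pd.DataFrame(rows, columns=["organ", "tau_h"]).to_csv(path, index=False)


def read_tiac_csv(path: str | Path, phantom: Phantom, cap_h: float | None = None) -> TIACTable:
    df = pd.read_csv(path)
    entries = {}
    remainder = 0.0
    for row in df.itertuples(index=False):
        if str(row.organ).upper() == "REMAINDER":
            remainder = float(row.tau_h)
        else:
            entries[str(row.organ)] = float(row.tau_h)
    return TIACTable(phantom=phantom, entries=entries, remainder_h=remainder, cap_h=cap_h)
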