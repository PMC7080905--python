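"""MIRD-schema absorbed dose engine.

The Medical Internal Radiation Dose (MIRD) formalism factorises the absorbed
dose to a target region into the kinetics (time-integrated activity tau per
source region) and the physics (the S value, absorbed dose in the target per
unit time-integrated activity in the source):

    D(r_T) = sum_S tau(r_S) * S(r_T <- r_S)        [mGy/MBq]

Effective dose follows from the ICRP tissue-weighting scheme,
E = sum_T w_T * H_T, with the weights summing to one.  For photon/positron
emitters the radiation weighting factor is 1, so mGy/MBq and mSv/MBq are
numerically identical.

The package ships small, openly constructed S-value matrices for its bundled
phantoms; a unit-density sphere self-dose fallback (non-penetrating component
only, local absorption) covers organs missing from a matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biodist import Isotope, ValidationError
from .tiac import REMAINDER, Phantom, TIACTable

__all__ = [
    "SValueMatrix",
    "TissueWeightingScheme",
    "DoseReport",
    "absorbed_doses",
    "effective_dose",
    "patient_dose",
    "sphere_self_dose_svalue",
    "load_svalue_matrix",
    "load_weights",
    "load_alias_map",
]

#: mGy per (MBq*h) per (MeV/decay) per gram:
#: 3.6e9 decays/MBq/h x 1.602e-13 J/MeV x 1000 g/kg x 1000 mGy/Gy
_SPHERE_K = 3.6e9 * 1.602e-13 * 1e3 * 1e3  # = 576.72


@dataclass(frozen=True)
class SValueMatrix:
    """Target <- source dose factors for one phantom, in mGy/(MBq*h)."""

    phantom_name: str
    targets: tuple[str, ...]
    sources: tuple[str, ...]
    values: np.ndarray  # shape (n_targets, n_sources)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.targets), len(self.sources)):
            raise ValidationError("S-matrix shape does not match its labels")
        if np.any(v < 0):
            raise ValidationError("S values must be >= 0")
        if len(set(self.targets)) != len(self.targets) or len(set(self.sources)) != len(self.sources):
            raise ValidationError("duplicate target or source labels")

    def s(self, target: str, source: str) -> float:
        return float(
            self.values[self.targets.index(target), self.sources.index(source)]
        )


@dataclass(frozen=True)
class TissueWeightingScheme:
    """ICRP tissue weighting factors w_T; must sum to 1.

    ``remainder_tissue`` names the weight entry that stands for all tissues
    not explicitly listed in a dose report; tissues in the scheme that are
    absent from a report also fall back to the report's remainder dose.
    """

    name: str
    weights: Mapping[str, float]
    remainder_tissue: str = REMAINDER

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"tissue weights must sum to 1, got {total:.8f}")
        for tissue, w in self.weights.items():
            if not 0 <= w <= 1:
                raise ValidationError(f"weight out of [0,1]: {tissue} = {w}")


@dataclass(frozen=True)
class DoseReport:
    """Organ absorbed doses (mGy/MBq) and effective dose (mSv/MBq)."""

    phantom_name: str
    organ_doses: Mapping[str, float]
    effective_dose: float | None = None
    assumptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for organ, d in self.organ_doses.items():
            if d < 0:
                raise ValidationError(f"dose must be >= 0: {organ} = {d}")
        if self.effective_dose is not None and self.effective_dose < 0:
            raise ValidationError("effective_dose must be >= 0")


def sphere_self_dose_svalue(mass_g: float, isotope: Isotope) -> float:
    """Self-dose S value of a unit-density sphere, mGy/(MBq*h).

    Assumes complete local absorption of the mean non-penetrating energy
    Delta_np = mean beta/positron energy x branching ratio; the photon
    cross-dose is deliberately excluded.  S = 576.7 x Delta_np / mass.
    """
    if mass_g <= 0:
        raise ValidationError(f"mass_g must be > 0, got {mass_g}")
    return _SPHERE_K * isotope.delta_np_mev / mass_g


def absorbed_doses(
    tiac: TIACTable,
    s: SValueMatrix,
    *,
    isotope: Isotope | None = None,
    aliases: Mapping[str, str] | None = None,
) -> DoseReport:
    """MIRD-schema organ doses: D(r_T) = sum_S tau(r_S) x S(r_T <- r_S).

    Every source in the TIAC table (including the remainder) must resolve —
    directly or through ``aliases`` — to an S-matrix source column.  If the
    matrix lacks a remainder column and an ``isotope`` is given, the remainder
    contributes self-dose only, via the sphere fallback evaluated at the
    phantom's unassigned mass.
    """
    aliases = aliases or {}
    assumptions: list[str] = []

    def resolve(name: str) -> str | None:
        for candidate in (name, aliases.get(name)):
            if candidate is not None and candidate in s.sources:
                return candidate
        return None

    doses = {t: 0.0 for t in s.targets}
    sources = dict(tiac.entries)
    sources[REMAINDER] = tiac.remainder_h
    for organ, tau in sources.items():
        col = resolve(organ)
        if col is None:
            if organ == REMAINDER and isotope is not None:
                rem_mass = tiac.phantom.remainder_mass_g
                if rem_mass <= 0:
                    raise ValidationError(
                        "phantom has no unassigned mass for the remainder fallback"
                    )
                s_rem = sphere_self_dose_svalue(rem_mass, isotope)
                doses.setdefault(REMAINDER, 0.0)
                doses[REMAINDER] += tau * s_rem
                assumptions.append(
                    "remainder of body: sphere self-dose fallback "
                    f"({rem_mass:.1f} g, non-penetrating component only; "
                    "photon cross-dose excluded)"
                )
                continue
            raise ValidationError(
                f"source organ {organ!r} has no column in the S matrix "
                f"(sources: {sorted(s.sources)})"
            )
        j = s.sources.index(col)
        for i, target in enumerate(s.targets):
            doses[target] += tau * float(s.values[i, j])
    return DoseReport(
        phantom_name=s.phantom_name,
        organ_doses=doses,
        assumptions=tuple(assumptions),
    )


def effective_dose(
    report: DoseReport,
    weights: TissueWeightingScheme,
    *,
    aliases: Mapping[str, str] | None = None,
) -> float:
    """Tissue-weighted effective dose E = sum_T w_T H_T, in mSv/MBq.

    With a radiation weighting factor of 1 the equivalent dose H_T equals the
    absorbed dose numerically.  Weighted tissues missing from the report take
    the report's remainder-of-body dose (the scheme's declared remainder
    rule); if no remainder dose exists either, a mapping error is raised.
    """
    aliases = aliases or {}
    doses = dict(report.organ_doses)
    remainder_dose = doses.get(REMAINDER)
    e = 0.0
    for tissue, w in weights.weights.items():
        d = doses.get(tissue)
        if d is None and tissue in aliases:
            d = doses.get(aliases[tissue])
        if d is None:
            if remainder_dose is None:
                raise ValidationError(
                    f"tissue {tissue!r} absent from the dose report and no "
                    "remainder dose is available"
                )
            d = remainder_dose
        e += w * d
    return e


def patient_dose(effective_dose_coeff: float, administered_mbq: float) -> float:
    """Whole-body effective dose (mSv) for an administered activity (MBq).

    The product of the effective-dose coefficient (mSv/MBq) and the
    administered activity, rounded to 3 significant figures as conventionally
    reported.
    """
    if effective_dose_coeff < 0 or administered_mbq < 0:
        raise ValidationError("coefficient and activity must be >= 0")
    dose = effective_dose_coeff * administered_mbq
    if dose == 0:
        return 0.0
    return float(np.format_float_positional(dose, precision=3, fractional=False))


# ---------------------------------------------------------------------------
# file formats


def load_svalue_matrix(path: str | Path, phantom_name: str | None = None) -> SValueMatrix:
    """Read an S matrix CSV: first column ``target``, one column per source."""
    df = pd.read_csv(path)
    if df.columns[0] != "target":
        raise ValidationError("S-matrix CSV must have 'target' as its first column")
    targets = tuple(str(t) for t in df["target"])
    sources = tuple(str(c) for c in df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return SValueMatrix(
        phantom_name=phantom_name or Path(path).stem,
        targets=targets,
        sources=sources,
        values=values,
    )


def load_weights(path: str | Path) -> TissueWeightingScheme:
    """Read a tissue-weighting JSON (``{name, weights: {...}, remainder_tissue?}``)."""
    with open(path) as fh:
        d = json.load(fh)
    return TissueWeightingScheme(
        name=d["name"],
        weights={k: float(v) for k, v in d["weights"].items()},
        remainder_tissue=d.get("remainder_tissue", REMAINDER),
    )


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read the explicit organ-name alias map (JSON object)."""
    with open(path) as fh:
        d = json.load(fh)
    return {str(k): str(v) for k, v in d.items()}


def write_dose_report(report: DoseReport, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    rows = sorted(report.organ_doses.items())
    df = pd.DataFrame(rows, columns=["organ", "dose_mgy_per_mbq"])
    if report.effective_dose is not None:
        df = pd.concat(
            [df, pd.DataFrame([("EFFECTIVE_DOSE", report.effective_dose)], columns=df.columns)],
            ignore_index=True,
        )
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "phantom": report.phantom_name,
                    "organ_doses_mgy_per_mbq": dict(sorted(report.organ_doses.items())),
                    "effective_dose_msv_per_mbq": report.effective_dose,
                    "assumptions": list(report.assumptions),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
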