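"""Access to the bundled dosimetric data files (phantoms, S matrices, weights)."""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .biodist import Isotope, load_isotope
from .dose import SValueMatrix, TissueWeightingScheme, load_alias_map, load_svalue_matrix, load_weights
from .qc import QCRun, ReleaseCriteria, load_criteria, read_qc_runs_csv
from .tiac import Phantom, load_phantom

__all__ = [
    "data_path",
    "default_isotope",
    "moby_phantom",
    "adult_phantom",
    "svalue_matrix",
    "icrp103_weights",
    "organ_aliases",
    "bundled_qc_runs",
    "bundled_qc_criteria",
]

_PHANTOM_FILES = {
    "moby25": "phantom_moby25.json",
    "adult_f": "phantom_adult_female.json",
    "adult_m": "phantom_adult_male.json",
}
_SVALUE_FILES = {
    "moby25": "svalues_moby25.csv",
    "adult_f": "svalues_adult_female.csv",
    "adult_m": "svalues_adult_male.csv",
}


def data_path(name: str) -> Path:
    p = files("biodosim").joinpath("data", name)
    return Path(str(p))


def default_isotope() -> Isotope:
    return load_isotope(data_path("isotope_f18.json"))


def moby_phantom() -> Phantom:
    return load_phantom(data_path(_PHANTOM_FILES["moby25"]))


def adult_phantom(sex: str) -> Phantom:
    key = "adult_f" if sex.upper().startswith("F") else "adult_m"
    return load_phantom(data_path(_PHANTOM_FILES[key]))


def svalue_matrix(which: str) -> SValueMatrix:
    if which not in _SVALUE_FILES:
        raise KeyError(f"unknown S matrix {which!r}; choose from {sorted(_SVALUE_FILES)}")
    return load_svalue_matrix(data_path(_SVALUE_FILES[which]), phantom_name=which)


def icrp103_weights() -> TissueWeightingScheme:
    return load_weights(data_path("weights_icrp103.json"))


def organ_aliases() -> dict[str, str]:
    return load_alias_map(data_path("organ_aliases.json"))


def bundled_qc_runs() -> list[QCRun]:
    return read_qc_runs_csv(data_path("qc_runs.csv"))


def bundled_qc_criteria() -> ReleaseCriteria:
    return load_criteria(data_path("qc_criteria.json"))
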