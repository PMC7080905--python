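"""Tests for the MIRD dose engine, effective dose and the sphere fallback."""

import numpy as np
import pytest

from biodosim.biodist import FLUORINE_18, Isotope, ValidationError
from biodosim.dose import (
    DoseReport,
    SValueMatrix,
    TissueWeightingScheme,
    absorbed_doses,
    effective_dose,
    patient_dose,
    sphere_self_dose_svalue,
)
from biodosim.resources import icrp103_weights, svalue_matrix
from biodosim.tiac import Phantom, TIACTable


def _table(entries, remainder=0.0):
    phantom = Phantom("toy", 1000.0, {k: 10.0 for k in entries})
    return TIACTable(phantom=phantom, entries=entries, remainder_h=remainder)


class TestAbsorbedDoses:
    def test_identity_matrix(self):
        s = SValueMatrix(
            "toy", ("liver", "kidneys", "remainder"), ("liver", "kidneys", "remainder"),
            np.eye(3),
        )
        report = absorbed_doses(_table({"liver": 0.5, "kidneys": 0.0}), s)
        assert report.organ_doses["liver"] == pytest.approx(0.5)
        assert report.organ_doses["kidneys"] == pytest.approx(0.0)

    def test_zero_tiacs_zero_doses(self):
        s = SValueMatrix(
            "toy", ("liver", "remainder"), ("liver", "remainder"), np.ones((2, 2))
        )
        report = absorbed_doses(_table({"liver": 0.0}), s)
        assert all(d == 0.0 for d in report.organ_doses.values())

    def test_two_by_two_hand_computed(self):
        # D = S tau with S = [[2,1],[0.5,3]] and tau = (0.1, 0.2)
        s = SValueMatrix(
            "toy", ("a", "b"), ("a", "b", "remainder"),
            np.array([[2.0, 1.0, 0.0], [0.5, 3.0, 0.0]]),
        )
        report = absorbed_doses(_table({"a": 0.1, "b": 0.2}), s)
        assert report.organ_doses["a"] == pytest.approx(0.4)
        assert report.organ_doses["b"] == pytest.approx(0.65)

    def test_unmapped_source_names_offender(self):
        s = SValueMatrix("toy", ("a",), ("a", "remainder"), np.array([[1.0, 0.0]]))
        with pytest.raises(ValidationError, match="mystery"):
            absorbed_doses(_table({"mystery": 0.1}), s)

    def test_alias_resolves_source(self):
        s = SValueMatrix("toy", ("lungs",), ("lungs", "remainder"), np.array([[2.0, 0.0]]))
        table = _table({"lung": 0.5})
        report = absorbed_doses(table, s, aliases={"lung": "lungs"})
        assert report.organ_doses["lungs"] == pytest.approx(1.0)

    def test_linearity_in_tiac(self):
        s = svalue_matrix("moby25")
        phantom = Phantom("toy", 25.0, {"pancreas": 0.3, "liver": 1.37})
        t1 = TIACTable(phantom, {"pancreas": 0.1, "liver": 0.05}, 0.2)
        t2 = TIACTable(phantom, {"pancreas": 0.2, "liver": 0.10}, 0.4)
        r1 = absorbed_doses(t1, s)
        r2 = absorbed_doses(t2, s)
        for organ in r1.organ_doses:
            assert r2.organ_doses[organ] == pytest.approx(
                2.0 * r1.organ_doses[organ], rel=1e-12
            )


class TestEffectiveDose:
    def test_uniform_dose_returns_itself(self):
        w = TissueWeightingScheme("toy", {"a": 0.5, "b": 0.3, "c": 0.2})
        report = DoseReport("toy", {"a": 2.0, "b": 2.0, "c": 2.0})
        assert effective_dose(report, w) == pytest.approx(2.0)

    def test_single_tissue_full_weight(self):
        w = TissueWeightingScheme("toy", {"a": 1.0})
        report = DoseReport("toy", {"a": 3.5, "b": 9.9})
        assert effective_dose(report, w) == pytest.approx(3.5)

    def test_three_tissue_weighted_sum(self):
        w = TissueWeightingScheme("toy", {"a": 0.5, "b": 0.3, "c": 0.2})
        report = DoseReport("toy", {"a": 1.0, "b": 2.0, "c": 3.0})
        assert effective_dose(report, w) == pytest.approx(1.7)

    def test_bounded_by_min_and_max_organ_dose(self, rng):
        w = icrp103_weights()
        for _ in range(20):
            doses = {t: float(rng.uniform(0.0, 5.0)) for t in w.weights}
            report = DoseReport("toy", doses)
            e = effective_dose(report, w)
            assert min(doses.values()) - 1e-12 <= e <= max(doses.values()) + 1e-12

    def test_missing_tissue_uses_remainder_dose(self):
        w = TissueWeightingScheme("toy", {"a": 0.5, "b": 0.5})
        report = DoseReport("toy", {"a": 1.0, "remainder": 0.4})
        assert effective_dose(report, w) == pytest.approx(0.5 * 1.0 + 0.5 * 0.4)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValidationError):
            TissueWeightingScheme("bad", {"a": 0.5, "b": 0.4})


class TestPatientDose:
    @pytest.mark.parametrize(
        "coeff, activity, expected",
        [
            (4.36e-3, 370.0, 1.61),   # F-18 peptide, male coefficient
            (2.57e-2, 185.0, 4.75),   # Ga-68 comparator coefficient
            (5.91e-3, 370.0, 2.19),   # female coefficient
            (1.0, 0.0, 0.0),
        ],
    )
    def test_reported_values(self, coeff, activity, expected):
        assert patient_dose(coeff, activity) == pytest.approx(expected, abs=5e-3)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            patient_dose(-1.0, 370.0)


class TestSphereSelfDose:
    def test_unit_energy_unit_mass(self):
        iso = Isotope("unit", 100.0, mean_np_energy_mev=1.0, beta_branching=1.0)
        assert sphere_self_dose_svalue(1.0, iso) == pytest.approx(576.7, abs=0.1)

    def test_inverse_mass_scaling(self, f18):
        assert sphere_self_dose_svalue(2.0, f18) == pytest.approx(
            sphere_self_dose_svalue(1.0, f18) / 2.0
        )

    def test_f18_100g(self, f18):
        assert sphere_self_dose_svalue(100.0, f18) == pytest.approx(1.395, abs=2e-3)

    def test_energy_bookkeeping_oracle(self, rng, f18):
        """Dose equals total decays x energy per decay / mass, computed independently."""
        for _ in range(50):
            tau_h = float(rng.uniform(0.01, 2.0))
            mass_g = float(rng.uniform(0.1, 500.0))
            dose = tau_h * sphere_self_dose_svalue(mass_g, f18)  # mGy/MBq
            decays = tau_h * 3600.0 * 1e6  # per MBq administered
            joules = decays * f18.delta_np_mev * 1.602e-13
            gray = joules / (mass_g * 1e-3)
            assert dose == pytest.approx(gray * 1e3, rel=1e-9)


class TestBundledDosimetryData:
    def test_icrp103_weights_sum_to_one(self):
        w = icrp103_weights()
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("which", ["moby25", "adult_f", "adult_m"])
    def test_self_dose_dominates_rows(self, which):
        s = svalue_matrix(which)
        for i, target in enumerate(s.targets):
            if target in s.sources:
                j = s.sources.index(target)
                row = s.values[i]
                assert row[j] >= row.max() - 1e-12
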