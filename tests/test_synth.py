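"""Tests for the synthetic-study generator and its ground-truth oracles."""

import math

import numpy as np
import pytest

from biodosim.biodist import apply_physical_decay, records_to_frame
from biodosim.kinetics import fit_tac
from biodosim.stats import two_sample_test
from biodosim.synth import OrganKinetics, SimConfig, simulate_study, true_tiac
from biodosim.tiac import Phantom, integrate_model


class TestSimulateStudy:
    def test_zero_noise_records_on_truth_curve(self, noiseless_study):
        cfg, records = noiseless_study
        for rec in records[::37]:
            kin = cfg.organs[rec.organ]
            expected = kin.value(rec.timepoint_h, rec.sex)
            if rec.blocked and kin.sstr2:
                expected *= cfg.blocked_residual_fraction
            assert rec.pct_id_g == pytest.approx(expected, rel=1e-12)

    def test_design_dimensions(self, noiseless_study):
        cfg, records = noiseless_study
        df = records_to_frame(records)
        # 4 unblocked groups + 1 blocked, 2 sexes, 8 animals, all organs
        n_groups = len(cfg.timepoints_h) + 1
        assert len(df) == n_groups * 2 * cfg.n_per_group * len(cfg.organs)
        assert set(df["sex"]) == {"F", "M"}
        assert df[df["blocked"] == 1]["timepoint_h"].unique().tolist() == [1.0]

    def test_seed_determinism(self):
        a = simulate_study(SimConfig(seed=5))
        b = simulate_study(SimConfig(seed=5))
        c = simulate_study(SimConfig(seed=6))
        assert a == b
        assert a != c

    def test_blocking_reduces_sstr2_organs_only(self, noiseless_study):
        cfg, records = noiseless_study
        df = records_to_frame(records)
        at_1h = df[(df["timepoint_h"] == cfg.blocked_timepoint_h) & (df["sex"] == "F")]
        for organ, kin in cfg.organs.items():
            base = at_1h[(at_1h["organ"] == organ) & (at_1h["blocked"] == 0)]["pct_id_g"].mean()
            blk = at_1h[(at_1h["organ"] == organ) & (at_1h["blocked"] == 1)]["pct_id_g"].mean()
            if kin.sstr2:
                assert blk == pytest.approx(base * cfg.blocked_residual_fraction, rel=1e-9)
            else:
                assert blk == pytest.approx(base, rel=1e-9)

    def test_lognormal_noise_cv_calibrated(self):
        """Empirical CV of 10,000 draws within 3% of the configured CV."""
        cfg = SimConfig(
            organs={"organ": OrganKinetics((10.0,), (0.5,))},
            timepoints_h=(1.0,),
            n_per_group=10_000,
            sexes=("F",),
            noise_cv=0.15,
            seed=3,
        )
        df = records_to_frame(simulate_study(cfg))
        vals = df[df["blocked"] == 0]["pct_id_g"].to_numpy()
        cv = vals.std(ddof=1) / vals.mean()
        assert cv == pytest.approx(0.15, rel=0.03)
        assert vals.mean() == pytest.approx(10.0 * math.exp(-0.5), rel=0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            SimConfig(noise_cv=-0.1)
        with pytest.raises(Exception):
            SimConfig(blocked_residual_fraction=1.5)


class TestTrueTiac:
    def test_pure_physical_decay_limit(self, f18):
        """Biological lambda ~ 0, A = 1 %ID/g, 100 g organ: tau = T1/2 / ln 2."""
        cfg = SimConfig(
            organs={"organ": OrganKinetics((1.0,), (1e-12,))}, isotope=f18
        )
        phantom = Phantom("toy", 1000.0, {"organ": 100.0})
        tau = true_tiac(cfg, "organ", phantom)
        assert tau == pytest.approx((109.77 / 60.0) / math.log(2.0), rel=1e-6)
        assert tau == pytest.approx(2.6395, abs=1e-4)

    def test_zero_amplitude_zero_tau(self, f18):
        cfg = SimConfig(organs={"organ": OrganKinetics((0.0,), (1.0,))}, isotope=f18)
        phantom = Phantom("toy", 1000.0, {"organ": 100.0})
        assert true_tiac(cfg, "organ", phantom) == 0.0

    def test_unknown_organ_rejected(self, moby):
        with pytest.raises(KeyError):
            true_tiac(SimConfig(), "no_such_organ", moby)

    def test_matches_fit_and_integrate_on_noiseless_data(self, noiseless_study, moby):
        """simulate -> decay -> fit -> integrate recovers the closed-form tau."""
        cfg, records = noiseless_study
        df = records_to_frame(records)
        for organ in ("pancreas", "liver", "blood", "kidneys", "muscle"):
            sub = df[(df["sex"] == "F") & (df["organ"] == organ) & (df["blocked"] == 0)]
            y = apply_physical_decay(
                sub["pct_id_g"].to_numpy(), sub["timepoint_h"].to_numpy(), cfg.isotope, "decay"
            )
            model = "bi" if len(cfg.organs[organ].rates) == 2 else "mono"
            fit = fit_tac(list(zip(sub["timepoint_h"], y)), model)
            tau = integrate_model(fit) * moby.mass(organ) / 100.0
            assert tau == pytest.approx(true_tiac(cfg, organ, moby, "F"), rel=1e-6)


class TestStudyLevelProperties:
    def test_blocking_detected_by_one_tail_t(self):
        """Receptor-positive organs at 1 h: blocked vs unblocked one-tail t, p < 0.001
        in >= 95% of seeds under default study conditions."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = records_to_frame(simulate_study(SimConfig(seed=seed)))
            at1 = df[(df["sex"] == "F") & (df["organ"] == "pancreas") & (df["timepoint_h"] == 1.0)]
            x = at1[at1["blocked"] == 0]["pct_id_g"].to_numpy()
            y = at1[at1["blocked"] == 1]["pct_id_g"].to_numpy()
            res = two_sample_test(x, y, tails="one", policy="t_pooled")
            hits += res.p_value < 0.001
        assert hits >= 0.95 * n_seeds

    def test_mono_lambda_recovery_unbiased(self):
        """200 studies at CV 15%, 8 animals x 4 time points: |lambda bias| < 5%."""
        cfg0 = SimConfig()
        lam_truth = cfg0.organs["pancreas"].rates[0] + cfg0.isotope.lambda_phys_per_h
        estimates = []
        for seed in range(200):
            cfg = SimConfig(seed=seed)
            df = records_to_frame(simulate_study(cfg))
            sub = df[(df["sex"] == "F") & (df["organ"] == "pancreas") & (df["blocked"] == 0)]
            y = apply_physical_decay(
                sub["pct_id_g"].to_numpy(), sub["timepoint_h"].to_numpy(), cfg.isotope, "decay"
            )
            fit = fit_tac(list(zip(sub["timepoint_h"], y)), "mono")
            estimates.append(fit.rates[0])
        bias = (np.mean(estimates) - lam_truth) / lam_truth
        assert abs(bias) < 0.05
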