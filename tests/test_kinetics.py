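"""Tests for TAC fitting and the R^2/residual-based model selection."""

import math

import numpy as np
import pytest

from biodosim.kinetics import (
    FitError,
    KineticFit,
    ValidationError,
    fit_tac,
    predict,
    runs_test_pvalue,
    select_model,
)

# observed group means for a receptor-rich organ at 0.5 and 1 h; with two
# points the mono fit has the closed form lambda = 2 ln(y1/y2), A = y1 e^{lambda/2}
PANCREAS_POINTS = [(0.5, 30.5), (1.0, 15.7)]
PANCREAS_LAMBDA = 2.0 * math.log(30.5 / 15.7)
PANCREAS_A = 30.5 * math.exp(PANCREAS_LAMBDA * 0.5)


class TestFitTac:
    def test_two_point_mono_closed_form(self):
        fit = fit_tac(PANCREAS_POINTS, "mono")
        assert fit.amplitudes[0] == pytest.approx(PANCREAS_A, rel=1e-6)
        assert fit.rates[0] == pytest.approx(PANCREAS_LAMBDA, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_bi_recovery(self):
        t = np.geomspace(0.25, 16.0, 8)
        y = 10.0 * np.exp(-0.8 * t) + 2.0 * np.exp(-0.1 * t)
        fit = fit_tac(list(zip(t, y)), "bi")
        assert fit.amplitudes == pytest.approx((10.0, 2.0), rel=1e-6)
        assert fit.rates == pytest.approx((0.8, 0.1), rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_activity_rejected(self):
        with pytest.raises(FitError):
            fit_tac([(0.5, 0.0), (1.0, 0.0), (2.0, 0.0)], "mono")

    def test_insufficient_points_rejected(self):
        with pytest.raises(FitError):
            fit_tac([(1.0, 2.0)], "mono")
        with pytest.raises(FitError):
            fit_tac([(0.5, 3.0), (1.0, 2.0), (2.0, 1.0)], "bi")
        with pytest.raises(FitError):
            fit_tac([(1.0, 2.0), (1.0, 2.1)], "mono")  # one distinct time

    def test_fit_invariant_to_point_permutation(self, rng):
        t = np.linspace(0.5, 8, 12)
        y = 5.0 * np.exp(-0.6 * t) * np.exp(rng.normal(0, 0.05, len(t)))
        pts = list(zip(t, y))
        f1 = fit_tac(pts, "mono")
        shuffled = [pts[i] for i in rng.permutation(len(pts))]
        f2 = fit_tac(shuffled, "mono")
        assert f1.amplitudes == f2.amplitudes and f1.rates == f2.rates

    def test_canonical_ordering_fast_first(self, rng):
        t = np.repeat(np.geomspace(0.25, 16, 8), 2)
        y = (8.0 * np.exp(-1.5 * t) + 1.0 * np.exp(-0.12 * t)) * np.exp(
            rng.normal(0, 0.05, len(t))
        )
        fit = fit_tac(list(zip(t, y)), "bi")
        assert fit.rates[0] > fit.rates[1]

    def test_group_means_collapses_replicates(self):
        pts = [(0.5, 30.0), (0.5, 31.0), (1.0, 15.0), (1.0, 16.4)]
        fit = fit_tac(pts, "mono", fit_on="group_means")
        assert fit.n_points == 2
        assert predict(fit, 0.5) == pytest.approx(30.5, rel=1e-6)

    def test_slow_rate_warns_below_physical_decay(self, f18):
        t = np.linspace(0.5, 8, 8)
        y = 5.0 * np.exp(-0.05 * t)  # slower than F-18 physical decay
        with pytest.warns(UserWarning, match="physical decay"):
            fit_tac(list(zip(t, y)), "mono", lambda_phys=f18.lambda_phys_per_h)


class TestPredict:
    def test_consistency_with_fit(self):
        fit = fit_tac(PANCREAS_POINTS, "mono")
        assert predict(fit, 0.5) == pytest.approx(30.5, rel=1e-9)
        assert predict(fit, 0.0) == pytest.approx(sum(fit.amplitudes), rel=1e-12)

    def test_asymptotic_decay_to_zero(self):
        fit = fit_tac(PANCREAS_POINTS, "mono")
        assert predict(fit, 40.0 / min(fit.rates)) < 1e-9

    def test_negative_time_rejected(self):
        fit = fit_tac(PANCREAS_POINTS, "mono")
        with pytest.raises(ValidationError):
            predict(fit, -1.0)


def _simulate_and_select(truth, cv, seed):
    t = np.linspace(0.5, 10.0, 32)
    sigma = math.sqrt(math.log1p(cv**2))
    rng = np.random.default_rng(seed)
    y = sum(a * np.exp(-l * t) for a, l in truth)
    y = y * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(t)))
    pts = list(zip(t, y))
    return select_model(fit_tac(pts, "mono"), fit_tac(pts, "bi"))


class TestSelectModel:
    def test_invalid_bi_candidate_falls_back_to_mono(self):
        t = np.linspace(0.5, 8, 8)
        y = 5.0 * np.exp(-0.5 * t)
        pts = list(zip(t, y))
        fit_mono = fit_tac(pts, "mono")
        # a bi candidate with an amplitude clamped to zero is not valid
        fit_bi = KineticFit(
            model="bi", amplitudes=(5.0, 0.0), rates=(0.5, 0.05),
            r_squared=1.0, residuals=tuple(0.0 for _ in pts), n_points=len(pts),
            converged=True, t_h=fit_mono.t_h, y=fit_mono.y,
        )
        assert select_model(fit_mono, fit_bi).model == "mono"

    def test_fits_on_different_data_rejected(self):
        f1 = fit_tac([(0.5, 4.0), (1.0, 2.0), (2.0, 1.0), (4.0, 0.4)], "mono")
        f2 = fit_tac([(0.5, 8.0), (1.0, 4.0), (2.0, 2.0), (4.0, 0.8)], "bi")
        with pytest.raises(ValidationError):
            select_model(f1, f2)

    def test_selection_never_worsens_r_squared(self, rng):
        for _ in range(20):
            t = np.linspace(0.5, 10, 16)
            y = (6.0 * np.exp(-1.0 * t) + 1.0 * np.exp(-0.1 * t)) * np.exp(
                rng.normal(0, 0.1, len(t))
            )
            pts = list(zip(t, y))
            fm = fit_tac(pts, "mono")
            chosen = select_model(fm, fit_tac(pts, "bi"))
            assert chosen.r_squared >= fm.r_squared

    def test_well_separated_bi_truth_selects_bi(self):
        """lambda1/lambda2 = 8, CV 5%, 32 points: bi chosen in >= 90% of seeds."""
        wins = sum(
            _simulate_and_select([(10.0, 0.8), (2.0, 0.1)], 0.05, s).model == "bi"
            for s in range(100)
        )
        assert wins >= 90

    def test_mono_truth_selects_mono(self):
        """Mono truth, CV 10%, 32 points: mono kept in >= 80% of seeds."""
        wins = sum(
            _simulate_and_select([(10.0, 0.5)], 0.10, s).model == "mono"
            for s in range(100)
        )
        assert wins >= 80


class TestRunsTest:
    def test_random_signs_pass(self, rng):
        r = rng.choice([-1.0, 1.0], size=24)
        r[0], r[1] = 1.0, -1.0  # guarantee both signs occur
        assert runs_test_pvalue(r) > 0.05

    def test_blocked_signs_fail(self):
        r = [1.0] * 10 + [-1.0] * 10
        assert runs_test_pvalue(r) < 0.01

    def test_near_zero_residuals_are_uninformative(self):
        r = [1e-14, -1e-14] * 8
        assert runs_test_pvalue(r, scale=1.0) == 1.0
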