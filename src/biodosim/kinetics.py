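"""Time-activity-curve fitting and model selection.

Organ uptake after a bolus injection is modelled as a sum of decaying
exponentials, y(t) = sum_i A_i exp(-lambda_i t) with A_i >= 0 and
lambda_i > 0.  Both a mono-exponential and a bi-exponential candidate are fit
by non-negative least squares; the better model is chosen on the coefficient
of determination combined with a runs-type randomness check on the residuals,
so a bi-exponential is only preferred when it both improves R^2 materially
and removes systematic structure the mono fit leaves behind.

Fits are deterministic: initial values come from a log-linear regression
(mono) or classical curve peeling (bi), with no random restarts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .biodist import ValidationError

__all__ = ["KineticFit", "FitError", "fit_tac", "select_model", "predict", "runs_test_pvalue"]

#: smallest admissible clearance rate (1/h); keeps the TAC integrable
RATE_FLOOR = 1e-4
#: minimum fast/slow rate ratio for a bi-exponential fit to count as resolved
RATE_SEPARATION_MIN = 3.0
#: default R^2 improvement a bi-exponential must show over the mono fit
DELTA_R2_MIN = 0.01


class FitError(RuntimeError):
    """Raised when a time-activity curve cannot be fit to the given points."""


@dataclass(frozen=True)
class KineticFit:
    """A fitted mono- or bi-exponential time-activity curve.

    Amplitudes are in %ID/g, rates in 1/h.  For ``model="bi"`` the components
    are canonically ordered with ``rates[0] > rates[1]`` (fast first).
    ``t_h``/``y`` retain the fitted data so model selection can verify both
    candidates saw the same points.
    """

    model: Literal["mono", "bi"]
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    r_squared: float
    residuals: tuple[float, ...]
    n_points: int
    converged: bool
    t_h: tuple[float, ...] = field(default=(), repr=False)
    y: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValidationError("amplitudes must be >= 0")
        if any(l <= 0 for l in self.rates):
            raise ValidationError("rates must be > 0")
        if self.model == "bi" and len(self.rates) == 2 and self.rates[0] <= self.rates[1]:
            raise ValidationError("bi fit requires canonical ordering rates[0] > rates[1]")
        if len(self.residuals) != self.n_points:
            raise ValidationError("residuals length must equal n_points")


def _tac(t: np.ndarray, amps: Sequence[float], rates: Sequence[float]) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for a, l in zip(amps, rates):
        out += a * np.exp(-l * t)
    return out


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mono-exponential starting values from a log-linear regression on y > 0."""
    pos = y > 0
    if pos.sum() >= 2 and len(np.unique(t[pos])) >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        lam = max(-slope, RATE_FLOOR)
        amp = math.exp(intercept)
    else:
        lam = math.log(2.0) / max(t.max(), 1e-6)
        amp = float(y.max())
    return amp, lam


def _peeling_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Bi-exponential starting values by curve peeling.

    Fit the slow component to the late half of the distinct time points, strip
    it, then fit the fast component to the positive early residuals.
    """
    ts = np.unique(t)
    split = ts[len(ts) // 2]
    late = t >= split
    a2, l2 = _loglinear_init(t[late], y[late])
    resid = y - a2 * np.exp(-l2 * t)
    early = (~late) & (resid > 0)
    if early.sum() >= 2 and len(np.unique(t[early])) >= 2:
        a1, l1 = _loglinear_init(t[early], resid[early])
    else:
        a1, l1 = max(y.max() - a2, 0.1 * y.max()), l2 * 10.0
    if l1 <= l2:
        l1 = l2 * 10.0
    return a1, l1, a2, l2


def _fit(t: np.ndarray, y: np.ndarray, x0: np.ndarray, n_comp: int) -> tuple[np.ndarray, bool]:
    def resid(p: np.ndarray) -> np.ndarray:
        return _tac(t, p[:n_comp], p[n_comp:]) - y

    lo = np.concatenate([np.zeros(n_comp), np.full(n_comp, RATE_FLOOR)])
    x0 = np.clip(x0, lo + 1e-12, np.inf)
    res = least_squares(
        resid, x0, bounds=(lo, np.inf), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20_000,
    )
    return res.x, bool(res.success)


def fit_tac(
    points: Sequence[tuple[float, float]],
    model: Literal["mono", "bi"],
    fit_on: Literal["individual", "group_means"] = "individual",
    lambda_phys: float | None = None,
) -> KineticFit:
    """Fit a mono- or bi-exponential TAC to (t_h, y) points by least squares.

    ``fit_on="group_means"`` collapses replicate measurements at each time
    point to their mean before fitting; ``"individual"`` (default) fits all
    points.  The fit is unweighted and deterministic given its inputs.
    """
    if model not in ("mono", "bi"):
        raise ValidationError(f"model must be 'mono' or 'bi', got {model!r}")
    pts = np.asarray(sorted(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be (t, y) pairs")
    t, y = pts[:, 0], pts[:, 1]
    if np.any(y < 0):
        raise FitError("negative y values are not a valid activity curve")
    if fit_on == "group_means":
        ts = np.unique(t)
        y = np.array([y[t == ti].mean() for ti in ts])
        t = ts
    n_min = 2 if model == "mono" else 4
    if len(t) < n_min:
        raise FitError(f"{model} fit needs >= {n_min} points, got {len(t)}")
    if len(np.unique(t)) < 2:
        raise FitError("need at least two distinct time points")
    if np.all(y == 0):
        raise FitError("all-zero activity: no decaying model exists")

    if model == "mono":
        a0, l0 = _loglinear_init(t, y)
        params, ok = _fit(t, y, np.array([a0, l0]), 1)
        amps, rates = (float(params[0]),), (float(params[1]),)
    else:
        a1, l1, a2, l2 = _peeling_init(t, y)
        params, ok = _fit(t, y, np.array([a1, a2, l1, l2]), 2)
        order = np.argsort(params[2:])[::-1]  # fast component first
        amps = tuple(float(params[i]) for i in order)
        rates = tuple(float(params[2 + i]) for i in order)

    if lambda_phys is not None and min(rates) < lambda_phys:
        # on physically-decayed data the slowest effective rate cannot fall
        # below the physical decay constant except through noise
        warnings.warn(
            f"fitted rate {min(rates):.4g}/h is below the physical decay "
            f"constant {lambda_phys:.4g}/h",
            stacklevel=2,
        )

    fitted = _tac(t, amps, rates)
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return KineticFit(
        model=model,
        amplitudes=amps,
        rates=rates,
        r_squared=r2,
        residuals=tuple(residuals),
        n_points=len(t),
        converged=ok,
        t_h=tuple(t),
        y=tuple(y),
    )


def runs_test_pvalue(residuals: Sequence[float], scale: float = 0.0) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs.

    Residuals within ``1e-9 * scale`` of zero are discarded (a numerically
    exact fit carries no sign information).  Returns 1.0 when fewer than 8
    signed residuals remain — too few for the normal approximation to have
    any power, so the sequence is treated as pattern-free.
    """
    r = np.asarray(residuals, dtype=float)
    tol = 1e-9 * (scale if scale > 0 else max(np.max(np.abs(r)), 1.0))
    signs = np.sign(r[np.abs(r) > tol])
    n = len(signs)
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n < 8 or n_pos == 0 or n_neg == 0:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def select_model(
    fit_mono: KineticFit,
    fit_bi: KineticFit,
    delta_r2_min: float = DELTA_R2_MIN,
    *,
    runs_alpha: float = 0.05,
    trace: list[str] | None = None,
) -> KineticFit:
    """Choose between the mono and bi candidates fitted to the same points.

    The bi-exponential wins only if it (a) converged with both amplitudes
    strictly positive and a fast/slow rate ratio of at least
    ``RATE_SEPARATION_MIN``, (b) improves R^2 by more than ``delta_r2_min``,
    and (c) the mono residual signs fail a runs test at ``runs_alpha`` while
    the bi residual signs pass it.  Otherwise the mono fit is kept.
    """
    if fit_mono.model != "mono" or fit_bi.model != "bi":
        raise ValidationError("select_model expects (mono fit, bi fit)")
    if fit_mono.t_h != fit_bi.t_h or fit_mono.y != fit_bi.y:
        raise ValidationError("candidate fits were made on different data")
    log = trace if trace is not None else []
    scale = max(fit_mono.y) if fit_mono.y else 0.0

    bi_valid = (
        fit_bi.converged
        and all(a > 0 for a in fit_bi.amplitudes)
        and fit_bi.rates[0] / fit_bi.rates[1] >= RATE_SEPARATION_MIN
    )
    log.append(f"bi candidate valid: {bi_valid}")
    if not bi_valid:
        log.append("selected mono (bi candidate invalid)")
        return fit_mono

    dr2 = fit_bi.r_squared - fit_mono.r_squared
    log.append(f"delta R^2 = {dr2:.5f} (threshold {delta_r2_min})")
    if dr2 <= delta_r2_min:
        log.append("selected mono (insufficient R^2 gain)")
        return fit_mono

    p_mono = runs_test_pvalue(fit_mono.residuals, scale)
    p_bi = runs_test_pvalue(fit_bi.residuals, scale)
    log.append(f"runs test p: mono {p_mono:.4f}, bi {p_bi:.4f} (alpha {runs_alpha})")
    if p_mono < runs_alpha <= p_bi:
        log.append("selected bi")
        return fit_bi
    log.append("selected mono (residual structure criterion not met)")
    return fit_mono


def predict(fit: KineticFit, t_h: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted curve sum_i A_i exp(-lambda_i t) at ``t_h`` >= 0."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t_h must be >= 0")
    out = _tac(t, fit.amplitudes, fit.rates)
    return float(out) if out.ndim == 0 else out


def fit_and_select(
    points: Sequence[tuple[float, float]],
    fit_on: Literal["individual", "group_means"] = "individual",
    delta_r2_min: float = DELTA_R2_MIN,
    trace: list[str] | None = None,
) -> KineticFit:
    """Fit both candidate models and apply the selection rule.

    If the bi-exponential cannot be attempted (fewer than 4 points) or fails
    to fit, the mono fit is returned directly.
    """
    fit_mono = fit_tac(points, "mono", fit_on)
    try:
        fit_bi = fit_tac(points, "bi", fit_on)
    except FitError:
        if trace is not None:
            trace.append("bi fit not attempted (insufficient points)")
        return fit_mono
    return select_model(fit_mono, fit_bi, delta_r2_min, trace=trace)
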