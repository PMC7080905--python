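"""Two-sample hypothesis tests used for blocking and toxicity comparisons.

Blocking studies compare tracer uptake in receptor-positive organs with and
without a saturating dose of the nonradioactive ligand; the conventional
analysis is a one-tail unpaired Student's t test on the two groups.  Toxicity
endpoints instead go through an assumption gate: samples that look normal
(Shapiro-Wilk) with equal variances (F ratio) get a pooled-variance t test,
anything else a Mann-Whitney rank-sum test — exact for small samples, normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .biodist import ValidationError

__all__ = ["TestResult", "t_test_from_summary", "two_sample_test"]

#: significance level for the normality / equal-variance gate
GATE_ALPHA = 0.05
#: largest combined sample size for which Mann-Whitney p is computed exactly
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison."""

    method: Literal["t_pooled", "t_welch", "mann_whitney"]
    statistic: float
    p_value: float
    tails: Literal["one", "two"]
    direction: Literal["greater", "less", "either"]
    df: float | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value out of [0,1]: {self.p_value}")
        if self.df is not None and self.df <= 0:
            raise ValidationError("df must be > 0 when present")


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    tails: Literal["one", "two"] = "one",
    variant: Literal["pooled", "welch"] = "pooled",
) -> TestResult:
    """Unpaired two-sample t test from group summaries (mean, SD, n).

    ``pooled`` uses the pooled variance s_p^2 with df = n1 + n2 - 2;
    ``welch`` the Welch-Satterthwaite approximation.  For ``tails="one"`` the
    p value is reported in the observed direction of the difference.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("t test requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be >= 0")
    notes: list[str] = []
    diff = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            notes.append("degenerate: zero variance and equal means; p = 1 by convention")
            return TestResult(
                method="t_pooled" if variant == "pooled" else "t_welch",
                statistic=0.0, p_value=1.0, tails=tails,
                direction="either", df=float(n1 + n2 - 2), notes=tuple(notes),
            )
        raise ValidationError("zero variance in both groups with unequal means")

    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        method: Literal["t_pooled", "t_welch"] = "t_pooled"
    elif variant == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        method = "t_welch"
    else:
        raise ValidationError(f"unknown variant {variant!r}")

    t = diff / se
    p_two = 2.0 * float(sps.t.sf(abs(t), df))
    if tails == "two":
        p = p_two
        direction: Literal["greater", "less", "either"] = "either"
    else:
        p = p_two / 2.0
        direction = "greater" if t >= 0 else "less"
    return TestResult(
        method=method, statistic=float(t), p_value=min(p, 1.0),
        tails=tails, direction=direction, df=df, notes=tuple(notes),
    )


def _mann_whitney(
    x: np.ndarray, y: np.ndarray, tails: Literal["one", "two"]
) -> TestResult:
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = (len(x) + len(y) <= EXACT_MW_MAX_N) and not has_ties
    method = "exact" if exact else "asymptotic"
    alternative = "two-sided"
    direction: Literal["greater", "less", "either"] = "either"
    if tails == "one":
        # test in the observed direction of the rank difference
        direction = "greater" if np.mean(sps.rankdata(np.concatenate([x, y]))[: len(x)]) >= np.mean(
            sps.rankdata(np.concatenate([x, y]))[len(x):]
        ) else "less"
        alternative = direction
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    notes = (f"mann-whitney p computed by {method} method",)
    return TestResult(
        method="mann_whitney", statistic=float(res.statistic),
        p_value=float(res.pvalue), tails=tails, direction=direction, notes=notes,
    )


def two_sample_test(
    x: Sequence[float],
    y: Sequence[float],
    tails: Literal["one", "two"] = "two",
    policy: Literal["auto", "t_pooled", "t_welch", "mann_whitney"] = "auto",
) -> TestResult:
    """Two-sample comparison with the normality/equal-variance gate.

    ``policy="auto"`` runs a Shapiro-Wilk normality check on each sample and
    a two-sided F-ratio variance check, all at alpha = 0.05: if every check
    passes the samples get a pooled-variance t test, otherwise Mann-Whitney.
    Explicit policies bypass the gate.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValidationError("samples must be non-empty")

    if policy in ("t_pooled", "t_welch"):
        return t_test_from_summary(
            float(np.mean(xa)), float(np.std(xa, ddof=1)), len(xa),
            float(np.mean(ya)), float(np.std(ya, ddof=1)), len(ya),
            tails=tails, variant="pooled" if policy == "t_pooled" else "welch",
        )
    if policy == "mann_whitney":
        return _mann_whitney(xa, ya, tails)
    if policy != "auto":
        raise ValidationError(f"unknown policy {policy!r}")

    if len(xa) < 3 or len(ya) < 3:
        raise ValidationError("auto policy requires n >= 3 per sample")

    notes: list[str] = []
    normal = True
    for label, sample in (("x", xa), ("y", ya)):
        if np.ptp(sample) == 0:
            normal = False
            notes.append(f"normality({label}): constant sample, gate fails")
            continue
        p_sw = float(sps.shapiro(sample).pvalue)
        notes.append(f"shapiro({label}) p = {p_sw:.4f}")
        normal &= p_sw >= GATE_ALPHA

    equal_var = True
    v1, v2 = np.var(xa, ddof=1), np.var(ya, ddof=1)
    if v1 > 0 and v2 > 0:
        f = v1 / v2
        d1, d2 = len(xa) - 1, len(ya) - 1
        p_f = 2.0 * min(float(sps.f.sf(f, d1, d2)), float(sps.f.cdf(f, d1, d2)))
        p_f = min(p_f, 1.0)
        notes.append(f"variance F-ratio p = {p_f:.4f}")
        equal_var = p_f >= GATE_ALPHA
    elif v1 != v2:
        equal_var = False
        notes.append("variance check: one sample is constant, gate fails")

    if normal and equal_var:
        res = t_test_from_summary(
            float(np.mean(xa)), float(np.std(xa, ddof=1)), len(xa),
            float(np.mean(ya)), float(np.std(ya, ddof=1)), len(ya),
            tails=tails, variant="pooled",
        )
        return TestResult(
            method=res.method, statistic=res.statistic, p_value=res.p_value,
            tails=res.tails, direction=res.direction, df=res.df,
            notes=tuple(notes) + res.notes,
        )
    notes.append("gate failed: falling back to Mann-Whitney")
    res = _mann_whitney(xa, ya, tails)
    return TestResult(
        method=res.method, statistic=res.statistic, p_value=res.p_value,
        tails=res.tails, direction=res.direction, notes=tuple(notes) + res.notes,
    )
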