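"""Group comparisons: unpaired t-tests and the force-ratio ~ sphericity
regression.

The default t-test variant is the pooled-variance (Student) test; Welch is
available by flag.  No multiple-testing correction is applied (four primary
comparisons reported as-is, alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import DomainError

__all__ = ["ComparisonResult", "ttest_unpaired", "ttest_from_summaries", "regress_ratio_si"]


@dataclass
class ComparisonResult:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    variant: str
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise DomainError(f"p-value {self.p} outside [0, 1]")


def ttest_from_summaries(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "student", metric: str = "",
) -> ComparisonResult:
    """Two-sided unpaired t-test from summary statistics (mean, SD, n)."""
    if n_a < 2 or n_b < 2:
        raise DomainError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if sd_a == 0.0 and sd_b == 0.0:
        # degenerate: identical constants -> no evidence of difference
        t = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        df = n_a + n_b - 2
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        res = sps.ttest_ind_from_stats(
            mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student")
        )
        t, p = float(res.statistic), float(res.pvalue)
        if variant == "student":
            df = n_a + n_b - 2
        else:
            va, vb = sd_a**2 / n_a, sd_b**2 / n_b
            df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return ComparisonResult(
        metric=metric, mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t=float(t), df=float(df), p=float(p), variant=variant,
    )


def ttest_unpaired(a, b, variant: str = "student", metric: str = "") -> ComparisonResult:
    """Two-sided unpaired t-test on two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("samples must be finite")
    return ttest_from_summaries(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        variant=variant, metric=metric,
    )


def regress_ratio_si(table, wave: str = "E") -> ComparisonResult:
    """OLS of the SAx-max/LAx-max ratio on the sphericity index, pooled over
    all subjects (both groups: the relation is tested across the spectrum)."""
    col = {"E": "ratio_e", "A": "ratio_a"}[wave.upper()]
    sub = table[[col, "si"]].dropna()
    if len(sub) < 3:
        raise DomainError("need >= 3 subjects with finite ratio and SI")
    si = sub["si"].to_numpy(float)
    ratio = sub[col].to_numpy(float)
    if np.ptp(si) == 0:
        raise DomainError("sphericity index is constant; regression undefined")
    res = sps.linregress(si, ratio)
    return ComparisonResult(
        metric=f"{col}~si",
        mean_a=float(ratio.mean()), sd_a=float(ratio.std(ddof=1)), n_a=len(sub),
        mean_b=float(si.mean()), sd_b=float(si.std(ddof=1)), n_b=len(sub),
        t=float(res.rvalue), df=float(len(sub) - 2), p=float(res.pvalue),
        variant="ols",
        slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2),
    )
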