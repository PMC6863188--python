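"""Between-group comparisons: Welch's t-test and Mann-Whitney U.

Cohort contrasts (HIV-infected vs uninfected, early vs deferred ART) are
run within explicit age windows, by default on log10(theta) because output
spans decades and is right-skewed. Both tests are implemented from their
defining formulas (Welch-Satterthwaite degrees of freedom; exact U-statistic
enumeration for small untied samples, normal approximation with tie and
continuity corrections otherwise); scipy serves as an independent
cross-check in the test suite. All p-values are two-sided and unadjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonSpec",
    "ComparisonResult",
    "welch_t",
    "mann_whitney",
    "compare_groups",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One planned contrast: which cohorts, which ages, which test."""

    group_a: str
    group_b: str
    age_window: tuple[float, float]  # [lo, hi) years
    measure: str = "theta"
    test: str = "welch"  # or "mann_whitney"
    log_transform: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.age_window
        if not lo < hi:
            raise ValueError(f"age_window must have lo < hi, got {self.age_window}")
        if self.group_a == self.group_b:
            raise ValueError("groups must be disjoint")
        if self.test not in ("welch", "mann_whitney"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class ComparisonResult:
    n_a: int
    n_b: int
    statistic: float
    p_two_sided: float
    degrees_of_freedom: Optional[float] = None
    mean_a: Optional[float] = None
    mean_b: Optional[float] = None
    median_a: Optional[float] = None
    median_b: Optional[float] = None
    test: str = ""

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def welch_t(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Unequal-variance two-sample t-test.

    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny), with Welch-Satterthwaite
    degrees of freedom and a two-sided p from the t distribution. When both
    samples have zero variance and equal means the comparison carries no
    evidence and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t-test needs n >= 2 per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        stat = 0.0 if mx == my else math.inf * math.copysign(1, mx - my)
        p = 1.0 if mx == my else 0.0
        return ComparisonResult(
            nx, ny, stat, p, degrees_of_freedom=float(nx + ny - 2),
            mean_a=mx, mean_b=my, test="welch",
        )
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(
        nx, ny, float(t), float(p), degrees_of_freedom=float(df),
        mean_a=float(mx), mean_b=float(my), test="welch",
    )


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of arrangements giving each U value, by the standard
    recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u)."""
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 20
) -> ComparisonResult:
    """Mann-Whitney U test (two-sided).

    U is the count of (x_i, y_j) pairs with x_i > y_j (ties count half).
    The p-value is exact — from the full null distribution of U — whenever
    both groups have at most ``exact_threshold`` observations and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections is used. Identical distributions of values give U at its
    null mean and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("Mann-Whitney needs n >= 1 per group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if not has_ties and n1 <= exact_threshold and n2 <= exact_threshold:
        counts = _u_counts(n1, n2)
        total = sum(counts)
        u_int = int(round(u1))
        cdf = sum(counts[: u_int + 1]) / total
        sf = sum(counts[u_int:]) / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean_u = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0 or u1 == mean_u:
            p = 1.0
        else:
            z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
            p = min(1.0, 2.0 * sps.norm.sf(z))
    return ComparisonResult(
        n1, n2, float(u1), float(p),
        median_a=float(np.median(x)), median_b=float(np.median(y)),
        test="mann_whitney",
    )


def compare_groups(
    samples: pd.DataFrame,
    spec: ComparisonSpec,
    group_col: str = "cohort",
    age_col: str = "age_years",
) -> ComparisonResult:
    """Filter by age window and cohort, then run the configured test."""
    lo, hi = spec.age_window
    in_window = (samples[age_col] >= lo) & (samples[age_col] < hi)
    vals = samples.loc[in_window, spec.measure]
    ok = vals.notna()
    if spec.log_transform:
        ok &= vals > 0
    windowed = samples.loc[in_window].loc[ok]
    groups = {}
    for label in (spec.group_a, spec.group_b):
        sel = windowed.loc[windowed[group_col] == label, spec.measure].to_numpy(float)
        if len(sel) == 0:
            raise ValueError(
                f"no {label!r} samples with {spec.measure!r} in age window "
                f"[{lo}, {hi}) years"
            )
        groups[label] = np.log10(sel) if spec.log_transform else sel
    a, b = groups[spec.group_a], groups[spec.group_b]
    if spec.test == "welch":
        return welch_t(a, b)
    return mann_whitney(a, b)
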