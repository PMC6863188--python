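"""Age-banded reference ranges and median quantile-regression age curves.

Reference ranges follow the pediatric convention: per age band, the median,
interquartile range and 5th-95th centiles of each measure, with band counts.
Quantiles use linear interpolation of order statistics (numpy's default,
the "type 7" rule), so tables are reproducible bit-for-bit.

Age curves are median (0.5-quantile) regressions of log10(value) on a
natural cubic spline of log10(age) — the log-log scale because the measures
span three orders of magnitude and change fastest in infancy. The fit
minimizes the check loss exactly via linear programming (HiGHS), and the
95% simultaneous confidence band comes from a subject-level bootstrap with
the sup-t (max absolute studentized deviation) construction, so the band
has joint coverage over the whole grid rather than pointwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "AgeBandScheme",
    "MedianCurve",
    "HEALTHY_BANDS",
    "HIV_ART_BANDS",
    "THETA_AGE_KNOTS",
    "age_knots",
    "reference_table",
    "fit_median_curve",
    "evaluate_curve",
    "simultaneous_band",
    "duplicate_sensitivity",
    "natural_spline_basis",
    "check_loss",
]

DAYS_PER_YEAR = 365.25
_MONTH_DAYS = DAYS_PER_YEAR / 12.0


@dataclass(frozen=True)
class AgeBandScheme:
    """Ordered age bands. Edges are in days; band i is [edge_i, edge_{i+1})
    except the last, which is closed at the top."""

    edges_days: tuple[int, ...]
    labels: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges_days) - 1:
            raise ValueError("need one label per band (len(edges) - 1)")
        if any(b <= a for a, b in zip(self.edges_days, self.edges_days[1:])):
            raise ValueError("edges must be strictly increasing")

    def assign(self, age_days) -> np.ndarray:
        """Band label per age; None for out-of-range ages."""
        a = np.asarray(age_days)
        idx = np.searchsorted(self.edges_days, a, side="right") - 1
        # the top edge belongs to the last band
        idx = np.where(a == self.edges_days[-1], len(self.labels) - 1, idx)
        out = np.where(
            (idx >= 0) & (idx < len(self.labels)),
            np.array(self.labels, dtype=object)[np.clip(idx, 0, len(self.labels) - 1)],
            None,
        )
        return out


def _months(*m: float) -> tuple[int, ...]:
    return tuple(int(round(x * _MONTH_DAYS)) for x in m)


HEALTHY_BANDS = AgeBandScheme(
    edges_days=_months(0, 3, 6, 12, 24, 72, 144),
    labels=("0-3 mo", "3-6 mo", "6-12 mo", "12-24 mo", "2-6 y", "6-12 y"),
    name="healthy-0-12y",
)

# Contiguous half-open version of the HIV-on-ART banding (the published
# layout leaves gaps between its upper bands; contiguity keeps band
# assignment exhaustive and exclusive).
HIV_ART_BANDS = AgeBandScheme(
    edges_days=_months(0, 3, 6, 12, 24, 48, 72, 96),
    labels=("0-3 mo", "3-6 mo", "6-12 mo", "12-24 mo", "2-4 y", "4-6 y", "6-8 y"),
    name="hiv-art-0-8y",
)


# Default interior knots (years) for output-vs-age curves: one inside the
# infancy rise, two bracketing the mid-childhood decline to plateau. Chosen
# by minimizing the natural-spline basis's approximation error to the
# unimodal peak-and-plateau curve family over 2 weeks-12 years; knot count
# is kept low because median-regression variance grows with basis size.
THETA_AGE_KNOTS = (0.3, 3.2, 6.5)


def age_knots(
    ages, interior: Sequence[float] = THETA_AGE_KNOTS
) -> np.ndarray:
    """Spline knots (log10 years) for an age curve: boundary knots at the
    data range, interior knots from ``interior`` kept strictly inside."""
    a = np.asarray(ages, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    inner = [k for k in interior if lo < k < hi]
    return np.log10(np.array([lo, *inner, hi]))


def reference_table(
    samples: pd.DataFrame,
    scheme: AgeBandScheme,
    measures: Sequence[str],
    age_col: str = "age_days",
) -> pd.DataFrame:
    """Per (band, measure): n, median, IQR and 5th-95th centiles.

    Rows with ages outside the scheme are logged and excluded; empty bands
    appear with n=0 and missing summaries. The result is invariant to the
    row order of ``samples``.
    """
    if age_col not in samples.columns:
        raise ValueError(f"missing age column {age_col!r}")
    bands = scheme.assign(samples[age_col].to_numpy())
    n_out = int(pd.isna(pd.Series(bands)).sum())
    if n_out:
        logger.warning(
            "%d samples outside band scheme %s excluded", n_out, scheme.name
        )
    rows = []
    for label in scheme.labels:
        in_band = samples.loc[bands == label]
        for measure in measures:
            vals = in_band[measure].dropna().to_numpy(dtype=float)
            if len(vals):
                q = np.quantile(vals, [0.05, 0.25, 0.5, 0.75, 0.95])
                summary = dict(
                    n=len(vals), p5=q[0], iqr_lo=q[1], median=q[2], iqr_hi=q[3], p95=q[4]
                )
            else:
                summary = dict(
                    n=0, p5=np.nan, iqr_lo=np.nan, median=np.nan,
                    iqr_hi=np.nan, p95=np.nan,
                )
            rows.append({"band": label, "measure": measure, **summary})
    cols = ["band", "measure", "n", "median", "iqr_lo", "iqr_hi", "p5", "p95"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# natural cubic spline basis (truncated-power construction with linearity
# constraints beyond the boundary knots; hand-built so a fitted curve is a
# plain (knots, coefficients) pair that serializes to JSON)

def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix [1, x, N_1(x), ..., N_{K-2}(x)] for K >= 3 knots."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if len(k) < 3:
        raise ValueError("need at least 3 knots (2 boundary + 1 interior)")

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - k[j], 0) ** 3 - np.maximum(x - k[-1], 0) ** 3
        return num / (k[-1] - k[j])

    d_last = d(len(k) - 2)
    cols = [np.ones_like(x), x]
    cols.extend(d(j) - d_last for j in range(len(k) - 2))
    return np.column_stack(cols)


def _quantile_knots(x: np.ndarray, n_interior: int) -> np.ndarray:
    probs = np.linspace(0, 1, n_interior + 2)
    knots = np.unique(np.quantile(x, probs))
    if len(knots) < 3:
        raise ValueError("degenerate design: too few distinct ages for a spline")
    return knots


def check_loss(residuals: np.ndarray, q: float = 0.5) -> float:
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0, q * r, (q - 1) * r)))


def _fit_quantile_lp(basis: np.ndarray, y: np.ndarray, q: float) -> np.ndarray:
    """Exact check-loss minimizer via the standard LP formulation:
    min q*1'u + (1-q)*1'v  s.t.  B(b+ - b-) + u - v = y, u,v >= 0."""
    n, p = basis.shape
    # unit-max column scaling keeps the simplex well conditioned
    scale = np.abs(basis).max(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    scaled = sparse.csc_matrix(basis / scale)
    eye = sparse.eye(n, format="csc")
    a_eq = sparse.hstack([scaled, -scaled, eye, -eye], format="csc")
    cost = np.concatenate([np.zeros(2 * p), q * np.ones(n), (1 - q) * np.ones(n)])
    res = linprog(cost, A_eq=a_eq, b_eq=y, method="highs")
    if not res.success:
        res = linprog(cost, A_eq=a_eq, b_eq=y, method="highs-ipm")
    if not res.success:  # pragma: no cover - two HiGHS algorithms both failed
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return (res.x[:p] - res.x[p : 2 * p]) / scale


@dataclass(frozen=True)
class MedianCurve:
    """A fitted quantile-regression age curve on the log-log scale.

    knots/coefficients define the natural-spline fit of log10(value) on
    log10(age); ``grid`` (years) and ``fitted`` (original scale) are its
    evaluation; band_lo/band_hi hold the simultaneous 95% limits once
    ``simultaneous_band`` has run.
    """

    knots: np.ndarray
    coefficients: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    quantile: float = 0.5
    band_lo: Optional[np.ndarray] = None
    band_hi: Optional[np.ndarray] = None
    band_level: float = 0.95
    n_boot: int = 0
    seed: Optional[int] = None

    def __call__(self, ages) -> np.ndarray:
        return evaluate_curve(self, ages)

    def to_dict(self) -> dict:
        out = {
            "knots_log10_age": list(map(float, self.knots)),
            "coefficients": list(map(float, self.coefficients)),
            "quantile": self.quantile,
            "grid_age_years": list(map(float, self.grid)),
            "fitted": list(map(float, self.fitted)),
            "band_level": self.band_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        if self.band_lo is not None:
            out["band_lo"] = list(map(float, self.band_lo))
            out["band_hi"] = list(map(float, self.band_hi))
        return out


def evaluate_curve(curve: MedianCurve, ages) -> np.ndarray:
    a = np.asarray(ages, dtype=float)
    basis = natural_spline_basis(np.log10(a), curve.knots)
    return 10.0 ** (basis @ curve.coefficients)


def fit_median_curve(
    ages,
    values,
    n_knots: int = 4,
    quantile: float = 0.5,
    grid: Optional[np.ndarray] = None,
    knots: Optional[np.ndarray] = None,
) -> MedianCurve:
    """Median quantile regression of log10(value) on a natural cubic spline
    of log10(age), with ``n_knots`` interior knots at age quantiles.

    Requires at least 10*(n_knots + 3) points (10 per effective parameter)
    and strictly positive values. The returned fit attains the minimal
    check loss in its basis span, so it is never worse than any constant.
    """
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(a) & np.isfinite(v)
    a, v = a[keep], v[keep]
    if np.any(v <= 0):
        raise ValueError("values must be > 0 for log-scale fitting")
    if np.any(a <= 0):
        raise ValueError("ages must be > 0")
    if a.size == 0:
        raise ValueError("no finite data points")
    if np.all(a == a[0]):
        raise ValueError("degenerate design: all ages equal")
    x = np.log10(a)
    kn = _quantile_knots(x, n_knots) if knots is None else np.asarray(knots, float)
    n_interior = len(kn) - 2
    min_n = 10 * (n_interior + 3)
    if len(a) < min_n:
        raise ValueError(
            f"need >= {min_n} points for {n_interior} interior knots, got {len(a)}"
        )
    beta = _fit_quantile_lp(natural_spline_basis(x, kn), np.log10(v), quantile)
    if grid is None:
        grid = np.geomspace(a.min(), a.max(), 50)
    grid = np.asarray(grid, dtype=float)
    fitted = 10.0 ** (natural_spline_basis(np.log10(grid), kn) @ beta)
    return MedianCurve(
        knots=kn, coefficients=beta, grid=grid, fitted=fitted, quantile=quantile
    )


def simultaneous_band(
    fit: MedianCurve,
    ages,
    values,
    subject_ids=None,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> MedianCurve:
    """Simultaneous confidence band around a fitted median curve.

    Bootstraps at subject level (clusters when ``subject_ids`` is given,
    rows otherwise), refits with the original knots, and builds the sup-t
    band: deviations on the log scale are studentized by the bootstrap
    pointwise sd, the ``level`` quantile of the maximal absolute deviation
    sets the common multiplier. The band always contains the point
    estimate. With all-zero noise in the data the bootstrap spread — and
    hence the band width — collapses to zero.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: band quantile will be coarse")
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    log_grid_fit = np.log10(fit.fitted)
    grid_basis = natural_spline_basis(np.log10(fit.grid), fit.knots)

    if subject_ids is None:
        groups = [np.array([i]) for i in range(len(a))]
    else:
        ids = pd.Series(subject_ids).reset_index(drop=True)
        groups = [idx.to_numpy() for _, idx in ids.groupby(ids).groups.items()]
    x_log, y_log = np.log10(a), np.log10(v)

    boot = np.empty((n_boot, len(fit.grid)))
    for b in range(n_boot):
        pick = rng.integers(len(groups), size=len(groups))
        rows = np.concatenate([groups[g] for g in pick])
        beta = _fit_quantile_lp(
            natural_spline_basis(x_log[rows], fit.knots), y_log[rows], fit.quantile
        )
        boot[b] = grid_basis @ beta

    sd = boot.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.finfo(float).tiny)
    t_stats = np.max(np.abs(boot - log_grid_fit) / sd, axis=1)
    t_crit = float(np.quantile(t_stats, level))
    half = t_crit * sd
    return replace(
        fit,
        band_lo=10.0 ** (log_grid_fit - half),
        band_hi=10.0 ** (log_grid_fit + half),
        band_level=level,
        n_boot=n_boot,
        seed=seed,
    )


def duplicate_sensitivity(
    samples: pd.DataFrame,
    value_col: str,
    seed: int = 0,
    age_col: str = "age_years",
    id_col: str = "subject_id",
    **fit_kwargs,
) -> tuple[MedianCurve, MedianCurve, float]:
    """Refit the median curve keeping one random sample per subject.

    Mirrors the repeated-measures check for longitudinal arms: duplicates
    are dropped at random (reproducibly under ``seed``), the curve is
    refitted with the same knots, and the maximum relative gap between the
    two curves over the evaluation grid is reported. With no duplicates the
    gap is exactly zero.
    """
    if id_col not in samples.columns:
        raise ValueError(f"missing subject id column {id_col!r}")
    curve_all = fit_median_curve(samples[age_col], samples[value_col], **fit_kwargs)
    rng = np.random.default_rng(seed)
    shuffled = samples.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
        drop=True
    )
    dedup = shuffled.groupby(id_col, sort=True).first().reset_index()
    if dedup.shape[0] == samples.shape[0]:
        return curve_all, curve_all, 0.0
    curve_dedup = fit_median_curve(
        dedup[age_col],
        dedup[value_col],
        knots=curve_all.knots,
        grid=curve_all.grid,
        quantile=curve_all.quantile,
    )
    gap = float(np.max(np.abs(curve_dedup.fitted - curve_all.fitted) / curve_all.fitted))
    return curve_all, curve_dedup, gap
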