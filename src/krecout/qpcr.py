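"""KREC quantification from real-time PCR readings.

KRECs (kappa-deleting recombination excision circles) are episomal DNA
circles formed during immunoglobulin kappa-locus rearrangement in precursor
B cells. They are quantified here by standard-curve qPCR alongside a diploid
housekeeping gene (TRAC, T cell receptor alpha-constant) that counts input
cells, and expressed in four interchangeable representations: per PBMC, per
mL of whole blood, per million B cells, and per million naive B cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StandardCurve",
    "QpcrReading",
    "CopiesResult",
    "KrecMeasures",
    "ct_to_copies",
    "copies_to_ct",
    "combine_replicates",
    "krec_per_pbmc",
    "convert_measures",
    "DEFAULT_STANDARD_CURVE",
]

# TRAC sits on a diploid autosome: two template copies per cell. Exposed so a
# lab calibrated against a single-copy standard can override it.
TRAC_COPIES_PER_CELL = 2.0


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(copies) calibration of one assay.

    slope      : Ct change per log10(copies); negative. slope = -3.3219
                 corresponds to 100% amplification efficiency.
    intercept  : Ct at a single copy.
    lower_limit: copies below which the assay reports non-detection.
    """

    slope: float
    intercept: float
    lower_limit: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        eff = 10.0 ** (-1.0 / self.slope) - 1.0
        if not 0.8 < eff < 1.1:
            raise ValueError(
                f"implied amplification efficiency {eff:.3f} outside (0.8, 1.1); "
                f"check slope {self.slope}"
            )
        if self.lower_limit < 0:
            raise ValueError("lower_limit must be >= 0")


# 100%-efficient assay (slope -1/log10(2)), Ct 40 at one copy: a typical
# TaqMan calibration.
DEFAULT_STANDARD_CURVE = StandardCurve(
    slope=-3.321928094887362, intercept=40.0, lower_limit=3.0
)


@dataclass(frozen=True)
class QpcrReading:
    """One well: KREC and TRAC cycle thresholds. ``krec_ct=None`` means the
    well never crossed threshold (non-detect)."""

    krec_ct: Optional[float]
    trac_ct: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        for name, ct in (("krec_ct", self.krec_ct), ("trac_ct", self.trac_ct)):
            if ct is not None and not (0 < ct <= 45):
                raise ValueError(f"{name}={ct} outside (0, 45]")


@dataclass(frozen=True)
class CopiesResult:
    """Copies per reaction with a censoring flag for non-detects."""

    copies: float
    censored: bool = False


def ct_to_copies(ct: Optional[float], curve: StandardCurve) -> CopiesResult:
    """Invert the standard curve: copies = 10**((ct - intercept) / slope).

    An undetermined Ct (None or NaN) is a non-detect and maps to 0 copies
    with ``censored=True``; so does a determined Ct implying fewer copies
    than the assay's lower limit.
    """
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return CopiesResult(0.0, censored=True)
    if ct <= 0:
        raise ValueError(f"Ct must be positive, got {ct}")
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    if copies < curve.lower_limit:
        return CopiesResult(0.0, censored=True)
    return CopiesResult(copies, censored=False)


def copies_to_ct(copies: float, curve: StandardCurve) -> Optional[float]:
    """Forward standard curve (used by the simulator). 0 copies -> None."""
    if copies < 0:
        raise ValueError(f"copies must be >= 0, got {copies}")
    if copies == 0:
        return None
    return curve.intercept + curve.slope * math.log10(copies)


def combine_replicates(
    cts: Sequence[Optional[float]],
    curve: StandardCurve,
    max_delta_ct: float = 1.5,
) -> tuple[CopiesResult, bool]:
    """Average replicate wells on the copies scale (not the Ct scale).

    Copies are exponential in Ct, so a mean of Cts would be a geometric mean
    of copies; the arithmetic mean of copies is the unbiased combination.
    Returns (combined result, qc_ok) where qc_ok is False when the spread of
    determined Cts exceeds ``max_delta_ct`` cycles. The combination is
    order-invariant. Censored wells contribute 0 copies; the result is
    censored only when every well is.
    """
    if len(cts) == 0:
        raise ValueError("no replicates supplied")
    results = [ct_to_copies(ct, curve) for ct in cts]
    determined = [ct for ct in cts if ct is not None and not math.isnan(ct)]
    qc_ok = (len(determined) < 2) or (max(determined) - min(determined) <= max_delta_ct)
    mean_copies = float(np.mean([r.copies for r in results]))
    return CopiesResult(mean_copies, censored=all(r.censored for r in results)), qc_ok


def krec_per_pbmc(
    krec_copies: float,
    trac_copies: float,
    trac_copies_per_cell: float = TRAC_COPIES_PER_CELL,
) -> float:
    """KREC copies per input cell: krec / (trac / copies-per-cell).

    TRAC is a diploid single-locus target, so trac_copies / 2 counts the
    PBMCs that went into the reaction. At most one KREC per rearranged
    allele, hence per_pbmc <= 2 for clean measurements.
    """
    if trac_copies <= 0:
        raise ValueError(
            "TRAC copies must be > 0 to quantify cell input; "
            f"got {trac_copies} (cell input unquantifiable)"
        )
    if krec_copies < 0:
        raise ValueError(f"krec_copies must be >= 0, got {krec_copies}")
    return krec_copies / (trac_copies / trac_copies_per_cell)


@dataclass(frozen=True)
class KrecMeasures:
    """The four KREC representations for one sample.

    per_ml_blood is None when no PBMC concentration is available (the CBC
    differential was not recorded on some stored specimens).
    """

    per_pbmc: float
    per_ml_blood: Optional[float]
    per_million_b: float
    per_million_naive_b: float


def convert_measures(
    per_pbmc: float,
    b_frac_of_pbmc: float,
    naive_frac_of_pbmc: float,
    pbmc_per_ml: Optional[float] = None,
) -> KrecMeasures:
    """Express a per-PBMC KREC content in the three derived representations.

    per_ml_blood       = per_pbmc * pbmc_per_ml            (None if no CBC)
    per_million_b      = per_pbmc / b_frac_of_pbmc * 1e6
    per_million_naive_b= per_pbmc / naive_frac_of_pbmc * 1e6

    Fractions are of PBMCs (lymphocytes + monocytes), so the two per-million
    measures satisfy per_million_b / per_million_naive_b = naive_frac / b_frac.
    """
    if per_pbmc < 0:
        raise ValueError(f"per_pbmc must be >= 0, got {per_pbmc}")
    for name, frac in (
        ("b_frac_of_pbmc", b_frac_of_pbmc),
        ("naive_frac_of_pbmc", naive_frac_of_pbmc),
    ):
        if not 0 < frac <= 1:
            raise ValueError(
                f"{name} must be in (0, 1] to normalize per-cell KREC content; got {frac}"
            )
    if pbmc_per_ml is not None and pbmc_per_ml <= 0:
        raise ValueError(f"pbmc_per_ml must be > 0, got {pbmc_per_ml}")
    per_ml = None if pbmc_per_ml is None else per_pbmc * pbmc_per_ml
    return KrecMeasures(
        per_pbmc=per_pbmc,
        per_ml_blood=per_ml,
        per_million_b=per_pbmc / b_frac_of_pbmc * 1e6,
        per_million_naive_b=per_pbmc / naive_frac_of_pbmc * 1e6,
    )
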