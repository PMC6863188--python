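"""Naive B cell output from KREC content and proliferation.

The central quantity is the daily bone-marrow output of naive B cells,

    theta(t) = y * N * tau / (Delta * (c - tau))

where ``y`` is the Ki67+ fraction of naive B cells (proliferation), ``N``
the total-body naive B cell pool, ``tau`` the KREC content per cell in the
periphery at sampling, ``c`` the KREC content per naive B cell as it enters
the periphery, and ``Delta`` the average division rate. KRECs are episomal
and not replicated at mitosis, so ``(c - tau)`` reflects the dilution of
KREC content by post-emigration division, and the formula converts a
standing pool with a given KREC content into a daily production rate.

``c`` and ``Delta`` are fixed constants taken from the naive T cell
literature (no direct B cell measurements exist); they rescale theta but do
not affect between-group contrasts. The formula is implemented exactly as
published, including Delta's position in the denominator; an alternative
Delta-in-numerator variant is available behind a switch but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qpcr import KrecMeasures

__all__ = [
    "ModelConstants",
    "OutputEstimate",
    "naive_b_output",
    "tau_from_measures",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the output formula.

    delta : average division rate of naive B cells, divisions/day.
    c     : KREC copies per naive B cell entering the peripheral pool.
    delta_in_numerator : if True, use the variant theta = y*N*tau*Delta/(c-tau)
        instead of the published form. Off by default.
    """

    delta: float = 0.52
    c: float = 0.6
    delta_in_numerator: bool = False

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not 0 < self.c <= 2:
            raise ValueError(f"c must be in (0, 2], got {self.c}")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class OutputEstimate:
    """One subject's naive B cell output and its ingredients.

    theta is in cells/day; ``valid`` is False when tau >= c (the model's
    domain boundary), in which case theta is NaN, never negative.
    """

    theta: float
    y: float
    n_total: float
    tau: float
    valid: bool
    age: float = float("nan")


def naive_b_output(
    y: float,
    n_total: float,
    tau: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    age: float = float("nan"),
) -> OutputEstimate:
    """Evaluate the output formula for one subject.

    Parameters
    ----------
    y : Ki67+ fraction of naive B cells, in [0, 1].
    n_total : total-body naive B cell pool, cells.
    tau : KREC copies per naive B cell in the periphery; must be >= 0 and,
        for a valid estimate, < ``constants.c``.

    Returns
    -------
    OutputEstimate with ``valid=False`` and ``theta=nan`` when tau >= c;
    out-of-range y, tau or n_total raise ValueError.
    """
    if not 0 <= y <= 1:
        raise ValueError(f"Ki67 fraction y must be in [0, 1], got {y}")
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if n_total < 0:
        raise ValueError(f"n_total must be >= 0, got {n_total}")
    if tau >= constants.c:
        return OutputEstimate(float("nan"), y, n_total, tau, valid=False, age=age)
    if constants.delta_in_numerator:
        theta = y * n_total * tau * constants.delta / (constants.c - tau)
    else:
        theta = y * n_total * tau / (constants.delta * (constants.c - tau))
    return OutputEstimate(theta, y, n_total, tau, valid=True, age=age)


def tau_from_measures(measures: KrecMeasures, basis: str = "per_naive_b") -> float:
    """Peripheral KREC content per cell, on the configured basis.

    ``per_naive_b`` (default) reads tau as KREC copies per naive B cell,
    i.e. per_million_naive_b / 1e6 — the same basis on which c = 0.6 is
    stated, so (c - tau) is a like-for-like difference. ``per_pbmc`` is the
    alternative reading (KRECs per PBMC); it is supported but yields tau
    values far below c for realistic samples.
    """
    if basis == "per_naive_b":
        if measures.per_million_naive_b is None:
            raise ValueError("per_million_naive_b required for basis 'per_naive_b'")
        return measures.per_million_naive_b / 1e6
    if basis == "per_pbmc":
        if measures.per_pbmc is None:
            raise ValueError("per_pbmc required for basis 'per_pbmc'")
        return measures.per_pbmc
    raise ValueError(f"unknown tau basis {basis!r}; use 'per_naive_b' or 'per_pbmc'")
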