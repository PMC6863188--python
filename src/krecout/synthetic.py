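"""Synthetic pediatric cohorts with a known ground-truth output curve.

The original cohorts — a healthy Child Wellness Clinic (CWC) reference
population (2 weeks to 12 years) and HIV-infected children from the CHER
trial arms (early-limited ART "ART-96W" and deferred ART "ART-Def") — were
never deposited. This module generates cohorts that emulate their structure:
an age-peaked true output curve theta*(a) with a steep rise to a peak in the
first year of life and decline to a late-childhood plateau, an HIV effect
multiplier, planned-ART schedules, and repeated sampling for the
longitudinal arm.

Every record is built to be internally consistent: with all measurement
noise at zero, pushing the record through the qPCR, flow-pool and output
modules returns exactly the true curve value at the subject's age. The
construction inverts the output formula — subject-level y and tau are drawn
from plausible biology, then the naive B cell concentration is solved so
that theta comes out at truth. Between-subject scatter of observed theta
around the age curve therefore comes from the measurement-noise model.

Noise placement keeps every quantity in its valid range: multiplicative
lognormal on cell counts, logit-normal on gating fractions, additive
Gaussian on Ct values. All noise distributions are median-preserving, so
the median observed theta at a given age tracks the true curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import flow, qpcr
from .model import DEFAULT_CONSTANTS, ModelConstants
from .qpcr import DEFAULT_STANDARD_CURVE, StandardCurve

__all__ = [
    "TrueCurveParams",
    "NoiseModel",
    "CohortDesign",
    "true_output_curve",
    "simulate_subject",
    "simulate_cohort",
    "weight_for_age",
    "cwc_design",
    "cher_96w_design",
    "cher_def_design",
    "DEFAULT_TRUE_CURVE",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class TrueCurveParams:
    """Ground-truth age -> output curve of the generator.

    The curve is theta*(a) = floor + (amplitude - floor) * g(a) with
    g(a) = (a/age_peak)**s * exp(s*(1 - a/age_peak)), s = decay_shape:
    unimodal with g(age_peak)=1 and g -> 0 at both ends, so the value at
    age_peak is exactly ``amplitude`` and the late-childhood asymptote is
    ``floor``. Defaults echo the printed healthy medians: ~8e8 cells/day at
    the year-1 peak, ~9e7 cells/day by late childhood.

    hiv_multiplier scales the whole curve for HIV-infected cohorts (>= 1,
    infected children have *higher* output than uninfected).
    """

    amplitude: float = 8e8
    age_peak: float = 1.0
    floor: float = 9e7
    decay_shape: float = 1.0
    hiv_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not self.amplitude > self.floor >= 0:
            raise ValueError(
                f"need amplitude > floor >= 0, got {self.amplitude}, {self.floor}"
            )
        if not self.age_peak > 0:
            raise ValueError(f"age_peak must be > 0, got {self.age_peak}")
        if not self.decay_shape > 0:
            raise ValueError(f"decay_shape must be > 0, got {self.decay_shape}")
        if not self.hiv_multiplier >= 1:
            raise ValueError(
                f"hiv_multiplier must be >= 1, got {self.hiv_multiplier}"
            )


DEFAULT_TRUE_CURVE = TrueCurveParams()


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings; identical seed implies identical cohort.

    cv_counts    : lognormal coefficient of variation on cell counts.
    cv_fractions : sd on the logit scale for gating fractions.
    sd_ct        : additive Gaussian sd on each replicate Ct, cycles.
    """

    cv_counts: float = 0.3
    cv_fractions: float = 0.3
    sd_ct: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("cv_counts", self.cv_counts),
            ("cv_fractions", self.cv_fractions),
            ("sd_ct", self.sd_ct),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def sigma_counts(self) -> float:
        """Lognormal sigma with the requested CV and median 1."""
        return math.sqrt(math.log1p(self.cv_counts**2))


ZERO_NOISE = NoiseModel(cv_counts=0.0, cv_fractions=0.0, sd_ct=0.0, seed=0)


@dataclass(frozen=True)
class CohortDesign:
    """Structure of one simulated cohort/arm.

    art_schedule is a list of (start_week, stop_week) age intervals of
    planned ART (empty for the uninfected cohort); a child is "on ART" at a
    sampling age falling inside any interval. For longitudinal designs,
    subjects enrol in ``enrol_age_weeks`` and contribute samples at trial
    weeks drawn from ``sampling_weeks``, ``n_samples`` in total, so subject
    ids repeat.
    """

    cohort_label: str
    n_subjects: int
    age_range: tuple[float, float]  # years
    art_schedule: tuple[tuple[float, float], ...] = ()
    hiv_infected: bool = False
    longitudinal: bool = False
    sampling_weeks: tuple[float, ...] = ()
    n_samples: Optional[int] = None
    enrol_age_weeks: tuple[float, float] = (6.0, 10.0)

    def __post_init__(self) -> None:
        if not self.n_subjects > 0:
            raise ValueError(f"n_subjects must be > 0, got {self.n_subjects}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must have min < max, got {self.age_range}")
        prev_stop = -math.inf
        for start, stop in self.art_schedule:
            if not start < stop:
                raise ValueError(f"empty ART interval ({start}, {stop})")
            if start < prev_stop:
                raise ValueError("ART intervals must be ordered and non-overlapping")
            prev_stop = stop
        if self.longitudinal:
            if not self.sampling_weeks:
                raise ValueError("longitudinal design needs sampling_weeks")
            if self.n_samples is not None and self.n_samples < self.n_subjects:
                raise ValueError("n_samples must be >= n_subjects")

    def on_art(self, age_years: float) -> bool:
        age_weeks = age_years * DAYS_PER_YEAR / DAYS_PER_WEEK
        return any(start <= age_weeks < stop for start, stop in self.art_schedule)


def cwc_design(n_subjects: int = 288) -> CohortDesign:
    """Healthy reference cohort: one visit each, 2 weeks to 12 years."""
    return CohortDesign(
        cohort_label="CWC",
        n_subjects=n_subjects,
        age_range=(14 / DAYS_PER_YEAR, 12.0),
    )


def cher_96w_design(n_subjects: int = 70, n_samples: int = 111) -> CohortDesign:
    """Early-limited-ART arm: ART from age ~7 weeks for 96 weeks, then a
    planned interruption (median ~70 weeks) before restart; repeated
    sampling at scheduled trial weeks."""
    return CohortDesign(
        cohort_label="ART-96W",
        n_subjects=n_subjects,
        age_range=(7 / 52.18, 8.0),
        art_schedule=((7.0, 103.0), (173.0, 1e6)),
        hiv_infected=True,
        longitudinal=True,
        sampling_weeks=(0.0, 4.0, 12.0, 40.0, 60.0, 96.0, 248.0, 360.0),
        n_samples=n_samples,
    )


def cher_def_design(n_subjects: int = 14) -> CohortDesign:
    """Deferred-ART arm: ART from age ~27 weeks, continuous thereafter."""
    return CohortDesign(
        cohort_label="ART-Def",
        n_subjects=n_subjects,
        age_range=(7 / 52.18, 8.0),
        art_schedule=((27.0, 1e6),),
        hiv_infected=True,
    )


def true_output_curve(age, params: TrueCurveParams = DEFAULT_TRUE_CURVE):
    """Ground-truth naive B cell output (cells/day) at ``age`` years.

    Vectorized over ``age``. The curve peaks exactly at ``params.age_peak``
    with value ``params.amplitude`` and decays to ``params.floor``.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    s = params.decay_shape
    rel = a / params.age_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(rel > 0, np.exp(s * (np.log(rel) + 1.0 - rel)), 0.0)
    value = params.floor + (params.amplitude - params.floor) * g
    return float(value) if np.isscalar(age) else value


# --- plausible-biology medians (subject-level truth, not measurement noise) ---
_Y_MEDIAN = 0.05          # Ki67+ fraction of naive B cells
_Y_LOGIT_SD = 0.4
_TAU_MEDIAN = 0.2         # KRECs per naive B cell in the periphery
_TAU_LOG_SD = 0.3
_TAU_MAX_FRAC_OF_C = 0.9  # regenerate draws at/above this fraction of c
_CD19_MEDIAN = 0.20       # B fraction of lymphocytes
_NAIVE_MEDIAN = 0.80      # IgD+CD27- fraction of CD19+
_BIO_LOGIT_SD = 0.25
_MONO_FRAC_OF_PBMC = 0.2
_WEIGHT_LOG_CV = 0.1
_CELLS_PER_REACTION = 2.5e4

_WEIGHT_AGES = np.array([0.0, 1.0, 5.0, 12.0])
_WEIGHT_KG = np.array([3.3, 9.5, 18.0, 40.0])


def weight_for_age(age_years: float) -> float:
    """Median weight-for-age, kg: piecewise linear through (0 y, 3.3 kg),
    (1 y, 9.5 kg), (5 y, 18 kg), (12 y, 40 kg)."""
    if age_years < 0:
        raise ValueError("age must be >= 0")
    return float(np.interp(age_years, _WEIGHT_AGES, _WEIGHT_KG))


def _logit_normal(rng: np.random.Generator, median: float, sd: float) -> float:
    if sd == 0:
        return median
    z = math.log(median / (1 - median)) + sd * rng.standard_normal()
    return 1.0 / (1.0 + math.exp(-z))


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if sigma == 0:
        return median
    return median * math.exp(sigma * rng.standard_normal())


def simulate_subject(
    age: float,
    design: CohortDesign,
    params: TrueCurveParams,
    noise: NoiseModel,
    rng: np.random.Generator,
    subject_id: str = "S0001",
    constants: ModelConstants = DEFAULT_CONSTANTS,
    standard_curve: StandardCurve = DEFAULT_STANDARD_CURVE,
) -> dict:
    """One blood sample, internally consistent with the true curve.

    Draws subject-level y and tau, solves the output formula for N, converts
    N to a naive B concentration via the blood-volume model, splits it into
    CBC counts and gating fractions, back-computes replicate Ct values
    through the standard curve, and finally perturbs every *observed*
    quantity with the measurement-noise model. Returns a flat dict (one CSV
    row) that also carries ``true_theta`` for recovery tests.
    """
    lo, hi = design.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside design range {design.age_range}")

    theta_true = true_output_curve(age, params)
    if design.hiv_infected:
        theta_true *= params.hiv_multiplier

    # subject-level biology
    y_true = _logit_normal(rng, _Y_MEDIAN, _Y_LOGIT_SD)
    tau_true = _lognormal(rng, _TAU_MEDIAN, _TAU_LOG_SD)
    for _ in range(100):
        if tau_true < _TAU_MAX_FRAC_OF_C * constants.c:
            break
        tau_true = _lognormal(rng, _TAU_MEDIAN, _TAU_LOG_SD)
    else:
        raise RuntimeError("could not draw tau < c; check tau/noise settings")

    weight_kg = _lognormal(
        rng, weight_for_age(age), math.sqrt(math.log1p(_WEIGHT_LOG_CV**2))
    )

    # invert theta = y*N*tau/(delta*(c-tau)) for N
    n_true = theta_true * constants.delta * (constants.c - tau_true) / (y_true * tau_true)
    volume_ul = flow.blood_volume_ul(weight_kg)
    naive_per_ul_true = n_true * flow.BLOOD_LYMPH_FRACTION / volume_ul

    cd19_true = _logit_normal(rng, _CD19_MEDIAN, _BIO_LOGIT_SD)
    naive_frac_true = _logit_normal(rng, _NAIVE_MEDIAN, _BIO_LOGIT_SD)
    lymph_true = naive_per_ul_true / (cd19_true * naive_frac_true)
    mono_true = lymph_true * _MONO_FRAC_OF_PBMC / (1 - _MONO_FRAC_OF_PBMC)
    lymph_frac_of_pbmc = lymph_true / (lymph_true + mono_true)

    # KREC side: per-PBMC content consistent with tau on the naive-B basis
    naive_frac_of_pbmc = lymph_frac_of_pbmc * cd19_true * naive_frac_true
    per_pbmc_true = tau_true * naive_frac_of_pbmc
    cells_per_reaction = _CELLS_PER_REACTION
    krec_copies = per_pbmc_true * cells_per_reaction
    trac_copies = qpcr.TRAC_COPIES_PER_CELL * cells_per_reaction
    krec_ct0 = qpcr.copies_to_ct(krec_copies, standard_curve)
    trac_ct0 = qpcr.copies_to_ct(trac_copies, standard_curve)

    # observed = truth + measurement noise
    sig = noise.sigma_counts
    record = {
        "subject_id": subject_id,
        "cohort": design.cohort_label,
        "hiv_infected": design.hiv_infected,
        "on_art": design.on_art(age),
        "age_days": int(round(age * DAYS_PER_YEAR)),
        "age_years": age,
        "weight_kg": weight_kg,
        "lymph_per_ul": _lognormal(rng, lymph_true, sig),
        "mono_per_ul": _lognormal(rng, mono_true, sig),
        "cd19_frac_of_lymph": _logit_normal(rng, cd19_true, noise.cv_fractions),
        "naive_frac_of_cd19": _logit_normal(rng, naive_frac_true, noise.cv_fractions),
        "ki67_frac_of_naive": _logit_normal(rng, y_true, noise.cv_fractions),
        "true_theta": theta_true,
    }
    for rep in (1, 2):
        record[f"krec_ct_{rep}"] = (
            float("nan")
            if krec_ct0 is None
            else krec_ct0 + noise.sd_ct * rng.standard_normal()
        )
        record[f"trac_ct_{rep}"] = trac_ct0 + noise.sd_ct * rng.standard_normal()
    return record


def _sample_ages(
    rng: np.random.Generator, n: int, age_range: tuple[float, float]
) -> np.ndarray:
    """Log-uniform ages: infancy, where the curve changes fastest, is dense."""
    lo, hi = age_range
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def simulate_cohort(
    design: CohortDesign,
    params: TrueCurveParams = DEFAULT_TRUE_CURVE,
    noise: NoiseModel = NoiseModel(),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    standard_curve: StandardCurve = DEFAULT_STANDARD_CURVE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort.

    Returns ``(samples, truth)``: the flat per-sample table and a truth
    table (subject_id, age_years, true_theta) for recovery tests. The
    output is a pure function of (design, params, noise) — the RNG is
    seeded from ``noise.seed`` and the cohort label.
    """
    label_mix = int.from_bytes(design.cohort_label.encode(), "little") % (2**20)
    rng = np.random.default_rng([noise.seed, label_mix])

    rows = []
    if design.longitudinal:
        n_samples = design.n_samples or design.n_subjects
        weeks = list(design.sampling_weeks)
        enrol_lo, enrol_hi = design.enrol_age_weeks
        enrol_ages = rng.uniform(enrol_lo, enrol_hi, size=design.n_subjects)
        # every subject contributes one scheduled visit; extras go to random
        # distinct (subject, week) pairs until n_samples is reached
        visits = {
            i: {int(rng.integers(len(weeks)))} for i in range(design.n_subjects)
        }
        n_assigned = design.n_subjects
        while n_assigned < n_samples:
            i = int(rng.integers(design.n_subjects))
            w = int(rng.integers(len(weeks)))
            if w not in visits[i]:
                visits[i].add(w)
                n_assigned += 1
        lo, hi = design.age_range
        for i in range(design.n_subjects):
            sid = f"{design.cohort_label}-{i + 1:04d}"
            for w in sorted(visits[i]):
                age = (enrol_ages[i] + weeks[w]) * DAYS_PER_WEEK / DAYS_PER_YEAR
                age = min(max(age, lo), hi)
                rows.append(
                    simulate_subject(
                        age, design, params, noise, rng, sid, constants, standard_curve
                    )
                )
    else:
        ages = _sample_ages(rng, design.n_subjects, design.age_range)
        for i, age in enumerate(ages):
            sid = f"{design.cohort_label}-{i + 1:04d}"
            rows.append(
                simulate_subject(
                    age, design, params, noise, rng, sid, constants, standard_curve
                )
            )

    samples = pd.DataFrame(rows)
    truth = samples[["subject_id", "age_years", "true_theta"]].copy()
    return samples, truth
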