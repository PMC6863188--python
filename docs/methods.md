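# Methods

## The output model

Naive B cell output (cells/day) is estimated as

    θ(t) = y · N · τ / (Δ · (c − τ))

The logic: *N·y* counts proliferating naive B cells in the whole body;
KRECs are not copied at mitosis, so the gap between the KREC content of
a fresh bone-marrow emigrant (*c*) and the content measured in the
periphery (*τ*) records how much division has diluted the label, and
Δ·(c − τ) converts that dilution into a time scale. The formula is
implemented exactly in this printed form. Dimensional analysis of the
printed expression actually yields cells·day with Δ in the denominator;
a Δ-in-numerator variant (`ModelConstants(delta_in_numerator=True)`) is
provided for sensitivity analyses but is off by default — fidelity to
the published estimator takes precedence over correcting it.

Domain: θ is defined for 0 ≤ τ < c, y ∈ [0,1], N ≥ 0. τ ≥ c produces a
*flagged invalid* estimate (NaN, `valid=False`), never a negative rate;
curve fits exclude invalid rows and the run manifest counts them.

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| Δ | average naive B division rate | 0.52 | divisions/day |
| c | KREC content of a new emigrant | 0.6 | copies/cell |
| lymph_fraction_in_blood | share of body lymphocytes in blood | 0.02 | – |
| volume model | log₁₀V(μL) = 0.97·log₁₀w(kg) + 4.93 | fixed | – |
| τ basis | per naive B cell (`per_million_naive_b`/10⁶) | config | copies/cell |

Δ and c are constants borrowed from naive T cell biology (no direct
B cell measurements exist); they rescale θ but cancel in between-group
contrasts. The volume bracket is read as log₁₀ of the volume in μL:
that reading gives 80 mL/kg in infants falling to ~70 mL/kg at 40 kg,
squarely physiological, whereas a natural-log reading is dimensionally
absurd. The τ basis question (per PBMC vs per naive B cell) is settled
in favour of per naive B cell because *c* is stated per naive B cell
entering the pool and (c − τ) is only meaningful on a shared basis;
realistic per-naive-cell contents (~0.1–0.5) then sit below c = 0.6,
while the per-PBMC alternative (~0.01–0.05) would make the dilution
correction nearly inert. Both bases are supported and the choice is
recorded in the run manifest.

## qPCR quantification

Copies per reaction come from a linear standard curve,
copies = 10^((Ct − intercept)/slope); the curve's implied amplification
efficiency must lie in (0.8, 1.1). Replicate wells are averaged on the
**copies** scale (copies are exponential in Ct, so averaging Ct would
give a geometric mean), with a QC flag when replicate Cts spread more
than 1.5 cycles. Undetermined wells are non-detects: 0 copies with a
censoring flag, and downstream summaries treat them as true zeros.
Cell input is counted by the TRAC housekeeping target at 2 copies per
diploid genome (configurable for labs calibrated against a single-copy
standard): per-PBMC content = KREC copies/(TRAC copies/2). The per-mL
representation requires a PBMC concentration from the CBC and is
nullable — stored specimens often lack it.

## Synthetic cohorts

The generator emulates the two study populations: a healthy reference
cohort (one visit per child, ages 2 weeks–12 years, default n=288,
log-uniform ages so infancy is dense) and HIV-infected trial arms
(early-limited ART from ~7 weeks with a planned interruption after 96
weeks, deferred ART from ~27 weeks; the early arm is longitudinal with
70 children contributing 111 samples at scheduled trial weeks).

Ground truth is the unimodal curve
θ*(a) = floor + (amplitude − floor)·(a/p)^s·exp(s(1 − a/p)), which
peaks exactly at *p* with value `amplitude` and decays to `floor`.
Defaults — amplitude 8×10⁸ cells/day, peak age 1 y, floor 9×10⁷,
shape s = 1, HIV multiplier 2 — place the healthy peak in the first
year and the plateau at late childhood, at the magnitudes the assay
literature reports for those ages, and give the infected arms the
elevated output that motivates the proliferation correction.

Each record is built by inversion: subject-level y (logit-normal,
median 0.05) and τ (lognormal, median 0.2, redrawn if ≥ 0.9c) are
drawn, then N — and from it the CBC and gating columns — is solved so
the noiseless record returns θ*(a) exactly; Ct values are back-computed
through the standard curve. Weight follows a piecewise-linear median
weight-for-age (3.3 kg at birth, 9.5 at 1 y, 18 at 5 y, 40 at 12 y).
Measurement noise is then applied where each quantity lives:
multiplicative lognormal on counts (CV 0.3), logit-normal on gating
fractions (sd 0.3), additive Gaussian on Ct (sd 0.15 cycles) — all
median-preserving, so the median observed θ at an age tracks the truth.

What the generator does **not** emulate: real between-subject biology
of θ around the age curve (all scatter is measurement-style noise, and
subject-level y/τ variation is absorbed into N by the inversion);
age-dependence of gating fractions and lymphocyte counts; viral loads,
CD4 trajectories or mortality; per-child ART adherence. Passing
recovery tests therefore demonstrate that the estimation chain is
faithful and the fitting machinery calibrated under a known truth —
not that real cohorts are this well behaved. One quantified
consequence: because several noise sources enter θ through the convex
τ/(c − τ) term, the median of observed θ sits ~5% above the true curve
at the default noise level; this distortion is inherent to measuring a
nonlinear functional under noise and is part of what the recovery
tolerance absorbs.

## Reference ranges and age curves

Reference tables report n, median, IQR and 5th–95th centiles per age
band and measure, using linear interpolation of order statistics
(numpy's default, "type 7") so tables reproduce bit for bit. Ages are
carried in integer days; bands are half-open [lo, hi) with the last
band closed, so every in-range age maps to exactly one band. The
healthy scheme uses 0–3/3–6/6–12/12–24 months, 2–6 and 6–12 years. The
published HIV-on-ART banding leaves gaps between its upper bands; the
shipped scheme (`hiv-art-0-8y`) uses contiguous bands
(…12–24 mo, 2–4, 4–6, 6–8 y) to keep banding exhaustive.

Age curves are 0.5-quantile (median) regressions of log₁₀(value) on a
natural cubic spline of log₁₀(age) — log scales because the measures
span three decades and change fastest in infancy, the median because
the distributions are heavy-tailed. The check loss is minimized exactly
by linear programming (HiGHS, unit-max column scaling, interior-point
fallback), so the fit is never worse than any constant and
interpolates in-span data exactly; statsmodels' IRLS `QuantReg` serves
as an independent cross-check in the tests. Default interior knots sit
at 0.3, 3.2 and 6.5 years (boundary knots at the data range): one knot
inside the infancy rise and two bracketing the decline-to-plateau.
They were chosen by minimizing the basis's approximation error to the
unimodal curve family above — quantile-placed knots underfit the
year-1 peak (approximation bias up to ~9%) — and the knot count is
kept low because median-regression variance grows with basis size.
Quantile placement remains available (`n_knots`, `curve_knots=None`).

The 95% band is **simultaneous** (joint over the whole age grid), not
pointwise: a subject-level bootstrap (clusters = children, so repeated
samples stay together) refits the curve with the original knots, and
the sup-t construction studentizes deviations by the bootstrap
pointwise sd and takes the 95th percentile of the maximal absolute
deviation as the common multiplier. Monte-Carlo calibration over
replicate cohorts (n=150, 150 bootstrap draws, 100–200 replicates —
the sizes all validation uses) put the joint coverage of the true
curve at ~94% for the sup-t band, with the unstudentized variant at
~97%; sup-t is the default. For degenerate inputs: all-equal ages or
nonpositive values on the log scale are rejected with explicit errors;
constant data yield a flat curve with zero loss; noiseless in-span
data collapse the band to zero width.

The duplicate-sensitivity check mirrors the repeated-measures concern
for the longitudinal arm: keep one random sample per child
(reproducible under a seed), refit with the same knots, and report the
maximum relative gap between the curves — compared in the analysis
against the band half-width.

## Cohort comparisons

Welch's t (Welch–Satterthwaite df) and Mann–Whitney U are implemented
from their defining formulas, two-sided, unadjusted, with scipy as the
reference in tests. Mann–Whitney p-values are exact — full null
distribution of U by the standard counting recurrence — whenever both
groups have ≤20 observations and no ties; otherwise the normal
approximation with tie and continuity corrections is used. Comparisons
run on log₁₀θ by default (θ spans decades and is right-skewed); both
groups with zero variance and equal means give p = 1 by convention.
Under the generator's null the empirical type-I error at α = 0.05 is
~4–6% for both tests, and a twofold HIV effect at n=60/arm in the 0–2
year window is detected essentially always (sizes: 300–500 null seeds,
150–200 alternative seeds).

## Known limitations

- Δ and c are T cell-derived constants; θ's absolute scale inherits
  their uncertainty (group contrasts do not).
- The printed formula's dimensional oddity is preserved by design.
- The generator's scatter is purely observational; real cohorts add
  biological dispersion the recovery tolerances do not model.
- With n ≈ 288 and the default noise, single-cohort median-curve
  recovery at six reference ages is accurate to roughly 10–15% —
  estimates at the age extremes carry the largest error.
- No mixed-effects modelling of repeated samples; the
  duplicate-sensitivity check is the only repeated-measures treatment.
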