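# krecout

Naive B cell output in children, estimated from KREC qPCR and flow
cytometry — with age-banded reference ranges, quantile-regression age
curves, and cohort comparisons.

## The problem

Kappa-deleting recombination excision circles (KRECs) are episomal DNA
circles created when precursor B cells rearrange the immunoglobulin
kappa locus in the bone marrow. They are not replicated at mitosis, so
each division of a naive B cell in the periphery dilutes its KREC
content. Raw KREC counts therefore confound bone-marrow output with
peripheral proliferation — a serious problem in conditions such as HIV
infection where proliferation is high.

This package implements a proliferation-corrected estimate of daily
naive B cell output:

    θ(t) = y · N · τ / (Δ · (c − τ))

where, at age *t*:

- *y* — fraction of naive (CD19⁺IgD⁺CD27⁻) B cells expressing Ki67,
- *N* — total-body naive B cell pool, scaled up from the blood
  concentration via a blood-volume-for-weight model
  (log₁₀ V(μL) = 0.97·log₁₀ weight(kg) + 4.93) and the assumption that
  ~2% of the body's lymphocytes circulate in blood,
- *τ* — KREC copies per naive B cell at sampling (from qPCR against a
  standard curve, cell input counted by the diploid TRAC housekeeping
  gene),
- *c* = 0.6 — KREC content of a naive B cell entering the periphery,
- *Δ* = 0.52/day — average division rate.

Around the estimator the package provides, for pediatric cohorts
(healthy reference children 2 weeks–12 years; HIV-infected children on
early-limited or deferred ART):

- the four standard KREC representations (per PBMC, per mL blood, per
  10⁶ B cells, per 10⁶ naive B cells),
- age-banded reference ranges (median [IQR], 5th–95th centiles),
- median quantile-regression age curves on the log–log scale with
  simultaneous 95% bootstrap bands,
- Welch and Mann–Whitney cohort comparisons in explicit age windows,
- a synthetic cohort generator with a known ground-truth output curve,
  so the whole chain is testable end to end: a noiseless synthetic
  record pushed through the pipeline returns the true curve *exactly*.

The intended users are immunology/biostatistics groups working with
excision-circle assays who need the estimator, its reference-range
machinery, and a validation harness in one place.

## Worked example

Generate a healthy cohort, quantify, and summarize (the `analysis/`
scripts run the same steps as a narrative pipeline):

```
$ krecout simulate --cohort cwc --seed 0 --out samples.csv
$ krecout quantify samples.csv --out annotated.csv
$ krecout curves annotated.csv --n-boot 500 --seed 0 --out curve.json
```

Running the analysis drivers end to end
(`python analysis/01_simulate_cohorts.py` … `05_compare_cohorts.py`)
prints, among other things:

```
CWC: naive B cell output (cells/day) by age band
     0-3 mo  n= 93  median 2.78e+08  IQR [1.65e+08, 4.19e+08]
    6-12 mo  n= 27  median 9.05e+08  IQR [5.68e+08, 1.17e+09]
     6-12 y  n= 42  median 1.04e+08  IQR [7.97e+07, 1.45e+08]
CWC: n=286, fitted peak at 1.01 y, median output there 9.40e+08 cells/day
ART-96W vs CWC (0-2 y, welch): n=73/190, ART-96W > CWC on log10(theta), p = 2.4e-26
```

Read: in the simulated healthy cohort, output rises through infancy to a
peak of ~9×10⁸ cells/day around one year of age and falls to ~10⁸ by
late childhood, and the HIV-infected arm (generated with a twofold
output multiplier) sits significantly above the healthy children in the
first two years — the estimator recovers both the shape and the group
contrast that were built into the simulation.

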