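"""Generate the study cohorts: healthy reference children (CWC-like,
n=288, 2 weeks-12 years) and HIV-infected children (ART-96W-like, 70
children contributing 111 scheduled samples; ART-Def-like, n=14), with a
known ground-truth output curve peaking at 8e8 cells/day in year one and a
twofold HIV multiplier.

Writes results/analysis/samples.csv and truth.csv.
"""

from pathlib import Path

import pandas as pd

from krecout import synthetic
from krecout.synthetic import NoiseModel, cher_96w_design, cher_def_design, cwc_design

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    noise = NoiseModel(seed=SEED)
    frames, truths = [], []
    for design in (cwc_design(), cher_96w_design(), cher_def_design()):
        s, t = synthetic.simulate_cohort(design, noise=noise)
        print(
            f"{design.cohort_label}: {len(s)} samples from "
            f"{s['subject_id'].nunique()} children, ages "
            f"{s['age_years'].min():.2f}-{s['age_years'].max():.1f} y, "
            f"{int(s['on_art'].sum())} on ART at sampling"
        )
        frames.append(s)
        truths.append(t)
    samples = pd.concat(frames, ignore_index=True)
    pd.concat(truths, ignore_index=True).to_csv(OUT / "truth.csv", index=False)
    samples.to_csv(OUT / "samples.csv", index=False)
    print(f"wrote {len(samples)} samples -> {OUT/'samples.csv'}")


if __name__ == "__main__":
    main()
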