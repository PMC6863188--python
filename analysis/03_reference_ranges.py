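"""Age-banded reference ranges (median [IQR], 5th-95th centiles) of the
four KREC representations and naive B cell output, per cohort.

Healthy children use 0-3/3-6/6-12/12-24 month and 2-6/6-12 year bands; the
HIV arms use contiguous bands to 8 years.

Reads results/analysis/samples_annotated.csv; writes reference_<cohort>.csv.
"""

from pathlib import Path

import pandas as pd

from krecout.curves import HEALTHY_BANDS, HIV_ART_BANDS, reference_table
from krecout.pipeline import REFERENCE_MEASURES

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    ann = pd.read_csv(OUT / "samples_annotated.csv")
    for cohort, scheme in (
        ("CWC", HEALTHY_BANDS),
        ("ART-96W", HIV_ART_BANDS),
        ("ART-Def", HIV_ART_BANDS),
    ):
        sub = ann[ann["cohort"] == cohort]
        tab = reference_table(sub, scheme, REFERENCE_MEASURES)
        path = OUT / f"reference_{cohort}.csv"
        tab.to_csv(path, index=False)
        theta = tab[tab.measure == "theta"].dropna()
        print(f"\n{cohort}: naive B cell output (cells/day) by age band")
        for _, r in theta.iterrows():
            print(f"  {r['band']:>9s}  n={int(r['n']):3d}  median {r['median']:.2e}  "
                  f"IQR [{r['iqr_lo']:.2e}, {r['iqr_hi']:.2e}]")
    print(f"\nwrote reference tables -> {OUT}")


if __name__ == "__main__":
    main()
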