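"""Between-group comparisons of naive B cell output: HIV-infected arms vs
healthy children in the first two years of life, on log10(theta), with
Welch's t-test and Mann-Whitney.

Reads results/analysis/samples_annotated.csv; writes comparisons.json.
"""

import json
from pathlib import Path

import pandas as pd

from krecout.stats import ComparisonSpec, compare_groups

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

SPECS = [
    ComparisonSpec("ART-96W", "CWC", (0.0, 2.0), test="welch"),
    ComparisonSpec("ART-96W", "CWC", (0.0, 2.0), test="mann_whitney"),
    ComparisonSpec("ART-Def", "CWC", (0.0, 2.0), test="welch"),
    ComparisonSpec("ART-96W", "ART-Def", (0.0, 2.0), test="mann_whitney"),
]


def main() -> None:
    ann = pd.read_csv(OUT / "samples_annotated.csv")
    ann = ann[ann["theta_valid"]]
    out = []
    for spec in SPECS:
        res = compare_groups(ann, spec)
        out.append({"spec": spec.__dict__, "result": res.to_dict()})
        loc_a = res.mean_a if res.mean_a is not None else res.median_a
        loc_b = res.mean_b if res.mean_b is not None else res.median_b
        direction = ">" if loc_a > loc_b else "<"
        print(
            f"{spec.group_a} vs {spec.group_b} ({spec.age_window[0]:.0f}-"
            f"{spec.age_window[1]:.0f} y, {spec.test}): "
            f"n={res.n_a}/{res.n_b}, {spec.group_a} {direction} {spec.group_b} "
            f"on log10(theta), p = {res.p_two_sided:.2g}"
        )
    (OUT / "comparisons.json").write_text(
        json.dumps(out, indent=1, sort_keys=True, default=list)
    )
    print(f"wrote -> {OUT/'comparisons.json'}")


if __name__ == "__main__":
    main()
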