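"""End-to-end orchestration: simulate/load -> quantify -> model -> report.

A single flat per-sample table (CSV, UTF-8, one row per blood sample) is the
interchange format between every stage; stages append derived columns and
never drop user columns. A run writes, under its output directory:

    samples.csv            the input table (simulated or copied through)
    truth.csv              ground truth (synthetic runs only)
    samples_annotated.csv  + KREC copies/measures, pool, tau, theta columns
    reference_<cohort>.csv Table-1-style banded reference ranges
    curve_<cohort>.json    median age curve + simultaneous band
    comparisons.json       configured between-group tests
    manifest.json          config hash, seed, versions, exclusion counts

Reruns with the same config and seed are byte-identical (the manifest
records no timestamps). Ages are carried in integer days internally; band
membership uses half-open day intervals, so band edges are unambiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, curves, flow, qpcr, synthetic
from .model import ModelConstants, naive_b_output, tau_from_measures
from .qpcr import StandardCurve
from .stats import ComparisonSpec, compare_groups

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_subject_table",
    "annotate_samples",
    "run_pipeline",
]

DAYS_PER_YEAR = 365.25

REQUIRED_COLUMNS = (
    "subject_id",
    "cohort",
    "weight_kg",
    "lymph_per_ul",
    "cd19_frac_of_lymph",
    "naive_frac_of_cd19",
    "ki67_frac_of_naive",
)

NUMERIC_COLUMNS = (
    "age_days",
    "age_years",
    "weight_kg",
    "lymph_per_ul",
    "mono_per_ul",
    "cd19_frac_of_lymph",
    "naive_frac_of_cd19",
    "ki67_frac_of_naive",
)

BAND_SCHEMES = {
    "healthy-0-12y": curves.HEALTHY_BANDS,
    "hiv-art-0-8y": curves.HIV_ART_BANDS,
}

REFERENCE_MEASURES = (
    "krec_per_pbmc",
    "krec_per_ml",
    "krec_per_million_b",
    "krec_per_million_naive_b",
    "theta",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; exactly one of input_path / synthetic."""

    out_dir: str
    seed: int = 0
    input_path: Optional[str] = None
    synthetic: Optional[dict] = None
    standard_curve: StandardCurve = qpcr.DEFAULT_STANDARD_CURVE
    constants: ModelConstants = ModelConstants()
    tau_basis: str = "per_naive_b"
    lymph_fraction: float = flow.BLOOD_LYMPH_FRACTION
    band_schemes: dict = field(
        default_factory=lambda: {
            "CWC": "healthy-0-12y",
            "ART-96W": "hiv-art-0-8y",
            "ART-Def": "hiv-art-0-8y",
        }
    )
    n_knots: int = 4
    curve_knots: Optional[tuple[float, ...]] = curves.THETA_AGE_KNOTS
    n_boot: int = 500
    comparisons: tuple[ComparisonSpec, ...] = ()

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of input_path / synthetic")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "standard_curve" in kw:
            kw["standard_curve"] = StandardCurve(**kw["standard_curve"])
        if "constants" in kw:
            kw["constants"] = ModelConstants(**kw["constants"])
        if "comparisons" in kw:
            kw["comparisons"] = tuple(
                ComparisonSpec(**{**c, "age_window": tuple(c["age_window"])})
                for c in kw["comparisons"]
            )
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample CSV, validating schema and numeric fields.

    Missing required columns raise a schema error naming them. Rows with
    malformed numeric fields are rejected individually (logged with their
    line numbers) and the rest kept. Unknown columns pass through.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if "age_days" not in df.columns and "age_years" not in df.columns:
        missing.append("age_days|age_years")
    ct_cols = [c for c in df.columns if c.startswith(("krec_ct", "trac_ct"))]
    copy_cols = [c for c in df.columns if c in ("krec_copies", "trac_copies")]
    if not ct_cols and len(copy_cols) < 2:
        missing.append("krec_ct*/trac_ct* or krec_copies/trac_copies")
    if missing:
        raise ValueError(f"subject table {path} missing required columns: {missing}")

    numeric = [
        c
        for c in df.columns
        if c in NUMERIC_COLUMNS or c.startswith(("krec_", "trac_")) or c == "true_theta"
    ]
    converted = df.copy()
    bad_rows: set[int] = set()
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        newly_bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        # undetermined Ct wells are a legal non-numeric entry
        if col.startswith("krec_ct"):
            newly_bad &= ~df[col].str.strip().str.lower().isin(
                {"undetermined", "nd", "na"}
            )
        bad_rows.update(df.index[newly_bad])
        converted[col] = vals
    if bad_rows:
        for idx in sorted(bad_rows):
            logger.warning("rejecting malformed row at line %d of %s", idx + 2, path)
        converted = converted.drop(index=sorted(bad_rows))
    for col in ("hiv_infected", "on_art"):
        if col in converted.columns:
            converted[col] = converted[col].astype(str).str.lower().isin(
                {"true", "1", "yes"}
            )
    if "age_days" not in converted.columns:
        converted["age_days"] = (
            converted["age_years"].astype(float) * DAYS_PER_YEAR
        ).round().astype(int)
    if "age_years" not in converted.columns:
        converted["age_years"] = converted["age_days"].astype(int) / DAYS_PER_YEAR
    logger.info("read %d samples from %s (%d rejected)", len(converted), path, len(bad_rows))
    return converted.reset_index(drop=True)


def _replicate_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    exact = [prefix] if prefix in df.columns else []
    numbered = sorted(c for c in df.columns if c.startswith(prefix + "_"))
    return exact + numbered


def annotate_samples(
    samples: pd.DataFrame,
    standard_curve: StandardCurve = qpcr.DEFAULT_STANDARD_CURVE,
    constants: ModelConstants = ModelConstants(),
    tau_basis: str = "per_naive_b",
    lymph_fraction: float = flow.BLOOD_LYMPH_FRACTION,
) -> pd.DataFrame:
    """Append all derived columns: KREC copies and the four measures, the
    naive pool, tau, and theta with its validity flag."""
    df = samples.copy()
    krec_cols = _replicate_columns(df, "krec_ct")
    trac_cols = _replicate_columns(df, "trac_ct")
    has_copies = "krec_copies" in df.columns and "trac_copies" in df.columns

    n = len(df)
    out = {
        k: np.full(n, np.nan)
        for k in (
            "krec_copies_mean",
            "trac_copies_mean",
            "krec_per_pbmc",
            "krec_per_ml",
            "krec_per_million_b",
            "krec_per_million_naive_b",
            "naive_per_ul",
            "blood_volume_ul",
            "n_total",
            "tau",
            "theta",
        )
    }
    censored = np.zeros(n, dtype=bool)
    qc_ok = np.ones(n, dtype=bool)
    valid = np.zeros(n, dtype=bool)

    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        if has_copies and np.isfinite(rec.get("krec_copies", np.nan)):
            kres = qpcr.CopiesResult(float(rec["krec_copies"]), censored=False)
            tcop = float(rec["trac_copies"])
        else:
            kres, kqc = qpcr.combine_replicates(
                [rec[c] for c in krec_cols], standard_curve
            )
            tres, tqc = qpcr.combine_replicates(
                [rec[c] for c in trac_cols], standard_curve
            )
            qc_ok[i] = kqc and tqc
            tcop = tres.copies
        censored[i] = kres.censored
        out["krec_copies_mean"][i] = kres.copies
        out["trac_copies_mean"][i] = tcop
        if tcop <= 0:
            continue
        per_pbmc = qpcr.krec_per_pbmc(kres.copies, tcop)

        lymph = float(rec["lymph_per_ul"])
        mono = float(rec.get("mono_per_ul") or 0.0)
        if not np.isfinite(mono):
            mono = 0.0
        pbmc_per_ul = lymph + mono
        lymph_frac_of_pbmc = lymph / pbmc_per_ul if pbmc_per_ul > 0 else np.nan
        cd19 = float(rec["cd19_frac_of_lymph"])
        naive = float(rec["naive_frac_of_cd19"])
        b_frac_of_pbmc = lymph_frac_of_pbmc * cd19
        naive_frac_of_pbmc = b_frac_of_pbmc * naive
        if not (np.isfinite(naive_frac_of_pbmc) and naive_frac_of_pbmc > 0):
            continue
        measures = qpcr.convert_measures(
            per_pbmc,
            b_frac_of_pbmc=b_frac_of_pbmc,
            naive_frac_of_pbmc=naive_frac_of_pbmc,
            pbmc_per_ml=pbmc_per_ul * 1000.0 if pbmc_per_ul > 0 else None,
        )
        out["krec_per_pbmc"][i] = measures.per_pbmc
        out["krec_per_ml"][i] = (
            np.nan if measures.per_ml_blood is None else measures.per_ml_blood
        )
        out["krec_per_million_b"][i] = measures.per_million_b
        out["krec_per_million_naive_b"][i] = measures.per_million_naive_b

        gating = flow.GatingSummary(cd19, naive, float(rec["ki67_frac_of_naive"]))
        pool = flow.pool_estimate(lymph, float(rec["weight_kg"]), gating, lymph_fraction)
        out["naive_per_ul"][i] = pool.naive_per_ul
        out["blood_volume_ul"][i] = pool.blood_volume_ul
        out["n_total"][i] = pool.n_total

        tau = tau_from_measures(measures, basis=tau_basis)
        est = naive_b_output(
            gating.ki67_frac_of_naive, pool.n_total, tau, constants,
            age=float(rec["age_years"]),
        )
        out["tau"][i] = tau
        out["theta"][i] = est.theta
        valid[i] = est.valid

    for k, v in out.items():
        df[k] = v
    df["krec_censored"] = censored
    df["qpcr_qc_ok"] = qc_ok
    df["theta_valid"] = valid
    return df


def _simulate_from_config(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    block = dict(cfg.synthetic or {})
    params = synthetic.TrueCurveParams(**block.get("params", {}))
    noise_kw = dict(block.get("noise", {}))
    noise_kw.setdefault("seed", cfg.seed)
    noise = synthetic.NoiseModel(**noise_kw)
    designs = []
    for d in block.get("designs", [{"kind": "cwc"}]):
        d = dict(d)
        kind = d.pop("kind", None)
        if kind == "cwc":
            designs.append(synthetic.cwc_design(**d))
        elif kind == "cher_96w":
            designs.append(synthetic.cher_96w_design(**d))
        elif kind == "cher_def":
            designs.append(synthetic.cher_def_design(**d))
        else:
            d["age_range"] = tuple(d["age_range"])
            if "art_schedule" in d:
                d["art_schedule"] = tuple(map(tuple, d["art_schedule"]))
            designs.append(synthetic.CohortDesign(**d))
    frames, truths = [], []
    for design in designs:
        s, t = synthetic.simulate_cohort(
            design, params, noise, cfg.constants, cfg.standard_curve
        )
        frames.append(s)
        truths.append(t)
    return (
        pd.concat(frames, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        samples, truth = _simulate_from_config(config)
        _write_csv(samples, out_dir / "samples.csv")
        _write_csv(truth, out_dir / "truth.csv")
    else:
        samples = read_subject_table(config.input_path)
        _write_csv(samples, out_dir / "samples.csv")

    annotated = annotate_samples(
        samples,
        standard_curve=config.standard_curve,
        constants=config.constants,
        tau_basis=config.tau_basis,
        lymph_fraction=config.lymph_fraction,
    )
    _write_csv(annotated, out_dir / "samples_annotated.csv")

    n_invalid_tau = int((~annotated["theta_valid"] & annotated["tau"].notna()).sum())
    n_censored = int(annotated["krec_censored"].sum())

    cohorts = sorted(annotated["cohort"].unique())
    reference_files = {}
    curve_files = {}
    dup_checks = {}
    rng = np.random.default_rng(config.seed)
    for cohort in cohorts:
        sub = annotated[annotated["cohort"] == cohort]
        scheme = BAND_SCHEMES[config.band_schemes.get(cohort, "healthy-0-12y")]
        ref = curves.reference_table(sub, scheme, REFERENCE_MEASURES)
        ref_path = out_dir / f"reference_{cohort}.csv"
        _write_csv(ref, ref_path)
        reference_files[cohort] = ref_path.name

        fit_data = sub[sub["theta_valid"] & (sub["theta"] > 0)]
        if config.curve_knots is not None:
            kn = curves.age_knots(fit_data["age_years"], config.curve_knots)
            fit_kw = {"knots": kn}
            min_n = 10 * (len(kn) + 1)
        else:
            fit_kw = {"n_knots": config.n_knots}
            min_n = 10 * (config.n_knots + 3)
        if len(fit_data) >= min_n:
            fit = curves.fit_median_curve(
                fit_data["age_years"], fit_data["theta"], **fit_kw
            )
            band_seed = int(rng.integers(2**31))
            fit = curves.simultaneous_band(
                fit,
                fit_data["age_years"],
                fit_data["theta"],
                subject_ids=fit_data["subject_id"],
                n_boot=config.n_boot,
                seed=band_seed,
            )
            curve_path = out_dir / f"curve_{cohort}.json"
            curve_path.write_text(json.dumps(fit.to_dict(), indent=1, sort_keys=True))
            curve_files[cohort] = curve_path.name
            if fit_data["subject_id"].duplicated().any():
                _, _, gap = curves.duplicate_sensitivity(
                    fit_data, "theta", seed=band_seed, **fit_kw
                )
                dup_checks[cohort] = gap

    comparisons = []
    for spec in config.comparisons:
        res = compare_groups(annotated[annotated["theta_valid"]], spec)
        comparisons.append({**dataclasses.asdict(spec), "result": res.to_dict()})
    (out_dir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=1, sort_keys=True)
    )

    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "tau_basis": config.tau_basis,
        "n_samples": int(len(annotated)),
        "n_schema_errors": 0,
        "n_invalid_tau": n_invalid_tau,
        "n_censored_krec": n_censored,
        "reference_tables": reference_files,
        "curves": curve_files,
        "duplicate_sensitivity_gap": dup_checks,
        "comparisons_file": "comparisons.json",
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
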