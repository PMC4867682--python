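"""Input validation, configuration, ingestion, and pipeline orchestration.

CSV dialect: comma-separated, UTF-8, dot decimal, ISO-8601 dates, one
header row plus an optional second row prefixed ``#units`` declaring a
unit per column (activity columns declared kBq or MBq are converted to
Bq at ingest).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .errors import DependencyError, SchemaError
from .flags import join_flags
from .kinetics import KineticsSeries, e_value_from_fit, fit_kinetics
from .partition import SeedPModel, fit_seed_model, ols_fit, partition_experiment
from .pools import pool_summary
from .tracer import P33_HALF_LIFE_DAYS, ActivityMeasurement, decay_correct

__all__ = [
    "RunConfig",
    "validate_table",
    "read_csv_with_units",
    "load_plants",
    "load_kinetics",
    "load_extractions",
    "run_pipeline",
    "regression_report",
]

_ACTIVITY_UNIT_SCALE = {"bq": 1.0, "kbq": 1e3, "mbq": 1e6}

SCHEMAS = {
    "plants": {
        "required": [
            "treatment",
            "soil",
            "replicate",
            "labeling",
            "dm_g_per_kg",
            "p_conc_mg_per_g",
            "activity_bq",
            "count_date",
        ],
        "numeric": ["dm_g_per_kg", "p_conc_mg_per_g", "activity_bq"],
    },
    "fertilizers": {
        "required": ["name", "dose"],
        "numeric": ["dose"],
    },
    "kinetics": {
        "required": [
            "sample_id",
            "treatment",
            "soil",
            "replicate",
            "t_min",
            "r_bq",
            "r_injected_bq",
            "c_p_mg_per_l",
        ],
        "numeric": ["t_min", "r_bq", "r_injected_bq", "c_p_mg_per_l"],
    },
    "extractions": {
        "required": [
            "sample_id",
            "treatment",
            "soil",
            "replicate",
            "day",
            "fumigated",
            "extract_p_mg_per_kg",
            "extract_activity_bq",
        ],
        "numeric": ["extract_p_mg_per_kg", "extract_activity_bq"],
    },
    "seed_experiment": {
        "required": ["rate", "replicate", "uptake", "pdf_seed"],
        "numeric": ["rate", "uptake", "pdf_seed"],
    },
}


@dataclass
class RunConfig:
    """Declarative run configuration; every field overridable by CLI flags."""

    half_life_days: float = P33_HALF_LIFE_DAYS
    reference_date: object = 0.0
    dose_mg_per_kg: float = datasets.DOSE_MG_P_PER_KG
    solution_soil_ratio: float = datasets.SOLUTION_SOIL_RATIO
    soil_total_p: float = datasets.SOIL_TOTAL_P
    soil_organic_p: float = datasets.SOIL_ORGANIC_P
    exclude_flagged: bool = True
    e_value_source: str = "fitted"
    reference_treatment: str = "MinP"
    nop_treatment: str = "NoP"
    sorption_factor: float = 1.0
    seed_model_a: float = 0.04
    seed_model_b: float = 0.5
    input_dir: str = "."
    out_dir: str = "out"
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "half_life_days",
            "dose_mg_per_kg",
            "solution_soil_ratio",
            "soil_total_p",
            "soil_organic_p",
        ):
            if getattr(self, name) <= 0:
                raise SchemaError([f"config: {name} must be > 0"])
        if self.e_value_source not in ("fitted", "raw"):
            raise SchemaError([f"config: unknown e_value_source {self.e_value_source!r}"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError([f"config: unknown keys {sorted(unknown)}"])
        return cls(**data)

    @property
    def seed_model(self) -> SeedPModel:
        return SeedPModel(a=self.seed_model_a, b=self.seed_model_b)

    @property
    def soil_pi(self) -> float:
        return self.soil_total_p - self.soil_organic_p


def read_csv_with_units(path) -> pd.DataFrame:
    """Read a CSV honoring the optional ``#units`` second row.

    Declared kBq/MBq activity columns are rescaled to Bq.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        second = fh.readline()
    units = None
    if second.startswith("#units"):
        cols = header.rstrip("\n").split(",")
        unit_cells = second.rstrip("\n").split(",")
        unit_cells[0] = unit_cells[0].replace("#units", "", 1)
        units = dict(zip(cols, unit_cells))
    df = pd.read_csv(path, comment="#")
    if units:
        for col, unit in units.items():
            scale = _ACTIVITY_UNIT_SCALE.get(unit.strip().lower())
            if scale is not None and scale != 1.0 and col in df.columns:
                df[col] = df[col] * scale
    return df


def validate_table(path, schema_name: str) -> pd.DataFrame:
    """Parse and validate an input CSV against a named schema.

    Raises SchemaError listing every violation (missing columns,
    non-numeric values, record-level invariants) with row numbers.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError([f"unknown schema {schema_name!r}"])
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise SchemaError([f"{path}: file does not exist"])
    df = read_csv_with_units(path)
    violations = []
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError([f"{path.name}: missing column(s) {missing}"])
    for col in schema["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            violations.append(f"{path.name} row {i + 2}: non-numeric {col} = {df.loc[i, col]!r}")
        df[col] = coerced

    if schema_name == "plants":
        neg = df.index[df["activity_bq"] < 0]
        for i in neg:
            violations.append(f"{path.name} row {i + 2}: negative activity_bq")
    if schema_name == "kinetics":
        for sid, g in df.groupby("sample_id"):
            t = g["t_min"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                rows = (g.index[1:][np.diff(t) <= 0] + 2).tolist()
                violations.append(
                    f"{path.name} sample {sid!r}: non-increasing t_min at row(s) {rows}"
                )
    if violations:
        raise SchemaError(violations)
    return df


# ---------------------------------------------------------------------------
# ingestion: raw CSV -> analysis-ready tables (decay-corrected, Bq, mg)


def load_plants(path, config: RunConfig) -> pd.DataFrame:
    df = validate_table(path, "plants")
    corrected = [
        decay_correct(
            ActivityMeasurement(row["activity_bq"], row["count_date"], config.reference_date),
            config.half_life_days,
        )
        for _, row in df.iterrows()
    ]
    df["activity"] = corrected
    df["uptake"] = df["dm_g_per_kg"] * df["p_conc_mg_per_g"]
    return df


def load_kinetics(path, config: RunConfig, doses: dict | None = None) -> list[KineticsSeries]:
    """One KineticsSeries per sample_id; Pi basis = soil Pi + treatment dose."""
    df = validate_table(path, "kinetics")
    doses = doses or {}
    series = []
    for sid, g in df.groupby("sample_id", sort=False):
        g = g.sort_values("t_min")
        treatment = str(g["treatment"].iloc[0])
        dose = doses.get(treatment, 0.0 if treatment == config.nop_treatment else config.dose_mg_per_kg)
        series.append(
            KineticsSeries(
                sample_id=str(sid),
                times=g["t_min"].to_numpy(dtype=float),
                r_t=g["r_bq"].to_numpy(dtype=float),
                r_injected=float(g["r_injected_bq"].iloc[0]),
                c_p=float(g["c_p_mg_per_l"].iloc[0]),
                pi_total=config.soil_pi + dose,
                ratio=config.solution_soil_ratio,
            )
        )
    return series


def load_extractions(path, config: RunConfig) -> pd.DataFrame:
    df = validate_table(path, "extractions")
    if "count_date" in df.columns:
        df["extract_activity_bq"] = [
            decay_correct(
                ActivityMeasurement(
                    row["extract_activity_bq"], row["count_date"], config.reference_date
                ),
                config.half_life_days,
            )
            for _, row in df.iterrows()
        ]
    return df.rename(
        columns={"extract_p_mg_per_kg": "extract_p", "extract_activity_bq": "extract_activity"}
    )


# ---------------------------------------------------------------------------
# pipeline


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages=("partition", "kinetics", "pools", "report")):
    """Run the selected stages in dependency order and write their outputs.

    Returns a run-log dict (also written as ``run_log.json``) recording
    input checksums, the effective configuration, and every flag raised.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    if "report" in stages and "partition" not in stages:
        raise DependencyError("the report stage requires the partition stage")

    needed = {
        "partition": ["plants.csv", "fertilizers.csv"],
        "kinetics": ["kinetics.csv"],
        "pools": ["extractions.csv"],
        "report": ["fertilizers.csv"],
    }
    missing = [
        f
        for st in stages
        for f in needed.get(st, [])
        if not (in_dir / f).exists()
    ]
    if missing:
        raise DependencyError(f"missing input file(s): {sorted(set(missing))}")

    log = {
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()},
        "inputs": {},
        "flags": [],
        "outputs": [],
    }
    flags_seen = []

    partition_summary = None
    if "partition" in stages:
        plants = load_plants(in_dir / "plants.csv", config)
        log["inputs"]["plants.csv"] = _checksum(in_dir / "plants.csv")
        ferts = read_csv_with_units(in_dir / "fertilizers.csv")
        log["inputs"]["fertilizers.csv"] = _checksum(in_dir / "fertilizers.csv")
        seed_csv = in_dir / "seed_experiment.csv"
        if seed_csv.exists():
            seed_df = validate_table(seed_csv, "seed_experiment")
            seed_model = fit_seed_model(seed_df["uptake"], seed_df["pdf_seed"])
            log["inputs"]["seed_experiment.csv"] = _checksum(seed_csv)
        else:
            seed_model = config.seed_model
        results, partition_summary = partition_experiment(
            plants,
            ferts,
            seed_model,
            exclude_flagged=config.exclude_flagged,
            reference_treatment=config.reference_treatment,
            nop_treatment=config.nop_treatment,
        )
        for fs in results["flags"]:
            for f in fs:
                flags_seen.append(f)
        results = results.assign(flags=results["flags"].map(join_flags))
        results.to_csv(out_dir / "partition_results.csv", index=False)
        partition_summary.to_csv(out_dir / "partition_summary.csv", index=False)
        log["outputs"] += ["partition_results.csv", "partition_summary.csv"]

    kinetics_out = None
    if "kinetics" in stages:
        series = load_kinetics(in_dir / "kinetics.csv", config)
        log["inputs"]["kinetics.csv"] = _checksum(in_dir / "kinetics.csv")
        rows = []
        for s in series:
            fit = fit_kinetics(s)
            e1 = e_value_from_fit(fit, s, source=config.e_value_source)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "m": fit.m,
                    "n": fit.n,
                    "e1min": e1,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            )
        kinetics_out = pd.DataFrame(rows)
        kinetics_out.to_csv(out_dir / "kinetics_fits.csv", index=False)
        log["outputs"].append("kinetics_fits.csv")

    pools_out = None
    if "pools" in stages:
        extracts = load_extractions(in_dir / "extractions.csv", config)
        log["inputs"]["extractions.csv"] = _checksum(in_dir / "extractions.csv")
        pools_out = pool_summary(
            extracts,
            nop_treatment=config.nop_treatment,
            sorption_factor=config.sorption_factor,
        )
        pools_out.to_csv(out_dir / "pool_summary.csv", index=False)
        log["outputs"].append("pool_summary.csv")

    if "report" in stages:
        ferts = read_csv_with_units(in_dir / "fertilizers.csv")
        report = regression_report(partition_summary, ferts)
        report.to_csv(out_dir / "regression_report.csv", index=False)
        log["outputs"].append("regression_report.csv")

    log["flags"] = sorted(set(flags_seen))
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


def regression_report(
    uptake_summary: pd.DataFrame,
    fertilizers: pd.DataFrame,
    incubation: pd.DataFrame | None = None,
    exclude=("NoP", "MinPdir"),
) -> pd.DataFrame:
    """Simple linear regressions of mean P uptake on candidate drivers.

    Fertilizer-fraction predictors: the H2O+NaHCO3-soluble and the
    HCl-soluble inorganic P fractions (treatments in ``exclude`` are
    left out).  When an incubation summary is supplied (columns matched
    by name per treatment x soil), its parameters are regressed too.
    p-values are descriptive; no multiple-testing correction.
    """
    up = uptake_summary[~uptake_summary["treatment"].isin(exclude)].copy()
    merged = up.merge(fertilizers, left_on="treatment", right_on="name", how="inner")
    merged["p_h2o_nahco3_pct"] = merged.get("p_h2o_pct", 0).fillna(0) + merged.get(
        "p_nahco3_pct", 0
    ).fillna(0)

    predictors = {"p_h2o_nahco3_pct": "H2O+NaHCO3-soluble Pi", "p_hcl_pct": "HCl-soluble Pi"}
    rows = []
    for soil, block in merged.groupby("soil", sort=False):
        for col, label in predictors.items():
            x = block[col].astype(float)
            y = block["uptake_mean"].astype(float)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                warnings.warn(f"{soil}: predictor {label!r} degenerate; skipped", stacklevel=2)
                continue
            fit = ols_fit(x[ok], y[ok])
            rows.append(
                {
                    "soil": soil,
                    "predictor": label,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                    "sign": "+" if fit.slope > 0 else "-",
                    "n": fit.n_points,
                }
            )
    if incubation is not None:
        inc_cols = [
            c
            for c in incubation.columns
            if c not in ("treatment", "soil") and pd.api.types.is_numeric_dtype(incubation[c])
        ]
        inc = incubation[~incubation["treatment"].isin(exclude)]
        m2 = up.merge(inc, on=["treatment", "soil"], how="inner")
        for soil, block in m2.groupby("soil", sort=False):
            for col in inc_cols:
                x = block[col].astype(float)
                y = block["uptake_mean"].astype(float)
                ok = x.notna() & y.notna()
                if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                    warnings.warn(f"{soil}: predictor {col!r} degenerate; skipped", stacklevel=2)
                    continue
                fit = ols_fit(x[ok], y[ok])
                rows.append(
                    {
                        "soil": soil,
                        "predictor": col,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "p_value": fit.p_value,
                        "sign": "+" if fit.slope > 0 else "-",
                        "n": fit.n_points,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["soil", "predictor", "slope", "intercept", "r_squared", "p_value", "sign", "n"],
    )
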