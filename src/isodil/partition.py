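"""Partitioning of plant P uptake into fertilizer-, soil-, and seed-derived
sources from isotope-dilution measurements.

Two labeling routes are supported.  With *direct* labeling the fertilizer
carries the tracer and the fertilizer-derived fraction follows from the
ratio of plant to fertilizer specific activity.  With *indirect* labeling
the plant-available soil pool is labeled, an unlabeled fertilizer dilutes
the plant specific activity relative to an unfertilized reference, and
fertilizer P is obtained by difference after correcting for the unlabeled
P supplied by the sown seed.

The seed correction is a linear model of seed-derived P versus uptake,
fitted on a direct-labeled sand-culture experiment in which seed P is the
only unlabeled source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import flags as F
from .errors import (
    DegenerateFitError,
    DegenerateReferenceError,
    InvalidParameterError,
    MissingReferenceError,
)

__all__ = [
    "SeedPModel",
    "SeedPPrediction",
    "FlaggedValue",
    "OLSResult",
    "fit_seed_model",
    "predict_seed_p",
    "seed_p_applied",
    "pdf_fertilizer_direct",
    "sa_noP_reference",
    "pdf_soil_indirect",
    "pdf_fertilizer_indirect",
    "fertilizer_recovery",
    "relative_agronomic_efficiency",
    "partition_experiment",
    "ols_fit",
]


@dataclass(frozen=True)
class SeedPModel:
    """Linear seed-contribution model ``pdf_seed = a * uptake + b``."""

    a: float
    b: float
    r_squared: float = 1.0
    n_points: int = 0


@dataclass(frozen=True)
class SeedPPrediction:
    value: float
    clamped: bool = False


@dataclass(frozen=True)
class FlaggedValue:
    """A numeric result carrying quality flags (kept, never dropped)."""

    value: float
    flags: frozenset = field(default_factory=frozenset)

    def __float__(self):
        return float(self.value)


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def ols_fit(x, y) -> OLSResult:
    """Ordinary least squares of y on x with the two-sided slope t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateFitError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in x")
    if np.ptp(y) == 0:
        # constant response: flat line, no explainable variance
        return OLSResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return OLSResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=int(x.size),
    )


def fit_seed_model(uptake, pdf_seed) -> SeedPModel:
    """Fit the seed-P calibration line on (uptake, seed-derived P) pairs."""
    fit = ols_fit(uptake, pdf_seed)
    return SeedPModel(a=fit.slope, b=fit.intercept, r_squared=fit.r_squared, n_points=fit.n_points)


def predict_seed_p(uptake: float, model: SeedPModel) -> SeedPPrediction:
    """Seed-derived P predicted at a given uptake, clamped at zero."""
    if uptake < 0:
        raise InvalidParameterError(f"uptake must be >= 0, got {uptake}")
    raw = model.a * uptake + model.b
    if raw < 0:
        return SeedPPrediction(value=0.0, clamped=True)
    return SeedPPrediction(value=raw, clamped=False)


def seed_p_applied(seed_mass_g: float, p_conc_mg_per_g: float) -> float:
    """P sown with the seeds (mg P) from seed dry mass and P concentration."""
    if seed_mass_g < 0 or p_conc_mg_per_g < 0:
        raise InvalidParameterError("seed mass and P concentration must be >= 0")
    return seed_mass_g * p_conc_mg_per_g


def pdf_fertilizer_direct(sa_plant: float, sa_fert: float, uptake: float) -> FlaggedValue:
    """Fertilizer-derived P under direct labeling: (SA_plant/SA_fert) x uptake.

    The plant specific activity cannot exceed that of the sole labeled
    source; if it does the value is kept but flagged IMPOSSIBLE_RATIO.
    """
    if sa_fert <= 0:
        raise InvalidParameterError(f"sa_fert must be > 0, got {sa_fert}")
    if uptake <= 0:
        raise InvalidParameterError(f"uptake must be > 0, got {uptake}")
    if sa_plant < 0:
        raise InvalidParameterError(f"sa_plant must be >= 0, got {sa_plant}")
    value = sa_plant / sa_fert * uptake
    fl = frozenset({F.IMPOSSIBLE_RATIO}) if sa_plant > sa_fert else frozenset()
    return FlaggedValue(value=value, flags=fl)


def sa_noP_reference(noP_records, seed_model: SeedPModel) -> float:
    """Reference specific activity of the labeled soil pool.

    Per unfertilized pot the SA is activity over seed-corrected uptake;
    the mean over replicates is returned.  ``noP_records`` is a DataFrame
    (or records) with ``uptake`` and ``activity`` columns.
    """
    df = pd.DataFrame(noP_records)
    if df.empty:
        raise MissingReferenceError("no unfertilized reference records supplied")
    sas = []
    for _, row in df.iterrows():
        uptake = float(row["uptake"])
        activity = float(row["activity"])
        seed = predict_seed_p(uptake, seed_model).value
        denom = uptake - seed
        if denom <= 0:
            raise DegenerateReferenceError(
                f"uptake {uptake} does not exceed predicted seed P {seed}"
            )
        sas.append(activity / denom)
    return float(np.mean(sas))


def pdf_soil_indirect(
    sa_plant_fertilized: float, sa_noP: float, uptake: float, pdf_seed: float
) -> float:
    """Soil-derived P under indirect labeling.

    ``sa_plant_fertilized`` must be computed on the same seed-corrected
    P basis as the reference (activity / (uptake - pdf_seed)) for the
    ratio to be an unbiased dilution measure.
    """
    if sa_noP <= 0:
        raise InvalidParameterError(f"sa_noP must be > 0, got {sa_noP}")
    if not (0 <= pdf_seed < uptake):
        raise InvalidParameterError(
            f"pdf_seed must satisfy 0 <= pdf_seed < uptake, got {pdf_seed} vs {uptake}"
        )
    return sa_plant_fertilized / sa_noP * (uptake - pdf_seed)


def pdf_fertilizer_indirect(uptake: float, pdf_soil: float, pdf_seed: float) -> FlaggedValue:
    """Fertilizer-derived P by difference; negative values are flagged."""
    if pdf_soil < 0 or pdf_seed < 0:
        raise InvalidParameterError("pdf_soil and pdf_seed must be >= 0")
    value = uptake - pdf_soil - pdf_seed
    fl = frozenset({F.NEGATIVE_PDF_FERTILIZER}) if value < 0 else frozenset()
    return FlaggedValue(value=value, flags=fl)


def fertilizer_recovery(pdf_fertilizer: float, dose: float) -> float:
    """Fertilizer-derived P as a percentage of the applied dose."""
    if dose <= 0:
        raise InvalidParameterError(f"dose must be > 0, got {dose}")
    return pdf_fertilizer / dose * 100.0


def relative_agronomic_efficiency(recovery_treatment: float, recovery_reference: float) -> float:
    """Recovery of a product as a percentage of the reference recovery."""
    if recovery_reference <= 0:
        raise InvalidParameterError(
            f"reference recovery must be > 0, got {recovery_reference}"
        )
    return recovery_treatment / recovery_reference * 100.0


# ---------------------------------------------------------------------------
# whole-experiment driver

_RESULT_COLUMNS = [
    "treatment",
    "soil",
    "replicate",
    "labeling",
    "uptake",
    "pdf_fertilizer",
    "pdf_soil",
    "pdf_seed",
    "pdf_fertilizer_pct",
    "recovery_pct",
    "rae_pct",
    "flags",
]


def _partition_one(row, sa_ref, fert_lookup, seed_model, nop_treatment):
    uptake = float(row["uptake"])
    activity = float(row["activity"])
    labeling = str(row.get("labeling", "indirect"))
    treatment = str(row["treatment"])
    pot_flags = set()

    pred = predict_seed_p(uptake, seed_model)
    if pred.clamped:
        pot_flags.add(F.CLAMPED_SEED_P)
    pdf_seed = pred.value

    fert = fert_lookup.get(treatment)
    dose = float(fert["dose"]) if fert is not None else np.nan

    if treatment == nop_treatment:
        pdf_fert = 0.0
        pdf_soil = uptake - pdf_seed
        recovery = np.nan
    elif labeling == "direct":
        if fert is None or not np.isfinite(fert.get("sa_fert", np.nan)):
            raise MissingReferenceError(
                f"direct-labeled treatment {treatment!r} lacks a fertilizer SA"
            )
        fv = pdf_fertilizer_direct(activity / uptake, float(fert["sa_fert"]), uptake)
        pot_flags |= fv.flags
        pdf_fert = fv.value
        pdf_soil = uptake - pdf_fert - pdf_seed
        recovery = fertilizer_recovery(pdf_fert, dose)
    else:  # indirect
        if sa_ref is None:
            raise MissingReferenceError(
                f"no unfertilized reference SA available for soil {row['soil']!r}"
            )
        denom = uptake - pdf_seed
        if denom <= 0:
            raise DegenerateReferenceError(
                f"uptake {uptake} does not exceed predicted seed P {pdf_seed}"
            )
        sa_plant = activity / denom
        pdf_soil = pdf_soil_indirect(sa_plant, sa_ref, uptake, pdf_seed)
        fv = pdf_fertilizer_indirect(uptake, pdf_soil, pdf_seed)
        pot_flags |= fv.flags
        pdf_fert = fv.value
        recovery = fertilizer_recovery(pdf_fert, dose) if np.isfinite(dose) else np.nan

    return {
        "treatment": treatment,
        "soil": row["soil"],
        "replicate": row.get("replicate"),
        "labeling": labeling,
        "uptake": uptake,
        "pdf_fertilizer": pdf_fert,
        "pdf_soil": pdf_soil,
        "pdf_seed": pdf_seed,
        "pdf_fertilizer_pct": pdf_fert / uptake * 100.0,
        "recovery_pct": recovery,
        "rae_pct": np.nan,
        "flags": pot_flags,
    }


def partition_experiment(
    plants: pd.DataFrame,
    fertilizers: pd.DataFrame,
    seed_model: SeedPModel,
    *,
    exclude_flagged: bool = True,
    reference_treatment: str = "MinP",
    nop_treatment: str = "NoP",
):
    """Partition every pot and summarise per treatment x soil.

    Parameters
    ----------
    plants : DataFrame
        Columns: treatment, soil, replicate, labeling (direct | indirect
        | none), uptake (mg P per kg soil), activity (Bq per kg soil,
        decay-corrected).
    fertilizers : DataFrame
        Columns: name, dose (mg P per kg soil); sa_fert (Bq per mg P)
        for direct-labeled products.
    seed_model : SeedPModel
        Calibration used to predict seed-derived P from uptake.
    exclude_flagged : bool
        Drop pots carrying excluding flags (e.g. negative fertilizer P)
        from summary statistics; they remain in the per-pot table.
    reference_treatment : str
        Treatment whose mean recovery anchors relative agronomic
        efficiency (reported as 100 by definition for itself).

    Returns
    -------
    (results, summary) : tuple of DataFrame
        Per-pot partition results and treatment x soil means/sds/counts.
    """
    plants = plants.copy()
    fert_lookup = {
        str(r["name"]): {"dose": r.get("dose", np.nan), "sa_fert": r.get("sa_fert", np.nan)}
        for _, r in fertilizers.iterrows()
    }

    rows = []
    for soil, soil_df in plants.groupby("soil", sort=False):
        nop = soil_df[soil_df["treatment"] == nop_treatment]
        has_indirect = (soil_df["labeling"] == "indirect").any()
        if nop.empty and has_indirect:
            raise MissingReferenceError(
                f"soil {soil!r} has indirect-labeled pots but no {nop_treatment!r} reference"
            )
        sa_ref = sa_noP_reference(nop, seed_model) if not nop.empty else None
        for _, row in soil_df.iterrows():
            rows.append(_partition_one(row, sa_ref, fert_lookup, seed_model, nop_treatment))

    results = pd.DataFrame(rows, columns=_RESULT_COLUMNS)

    # relative agronomic efficiency against the per-soil mean reference recovery
    for soil, idx in results.groupby("soil", sort=False).groups.items():
        block = results.loc[idx]
        ref = block[
            (block["treatment"] == reference_treatment)
            & (block["labeling"] == "indirect")
        ]
        if exclude_flagged:
            ref = ref[~ref["flags"].apply(lambda s: bool(s & F.EXCLUDING_FLAGS))]
        if ref.empty:
            warnings.warn(
                f"soil {soil!r}: no {reference_treatment!r} pots; RAE omitted", stacklevel=2
            )
            continue
        ref_recovery = float(ref["recovery_pct"].mean())
        for i in idx:
            r = results.loc[i]
            if r["treatment"] == reference_treatment and r["labeling"] == "indirect":
                results.loc[i, "rae_pct"] = 100.0  # by definition
            elif np.isfinite(r["recovery_pct"]) and r["treatment"] != nop_treatment:
                results.loc[i, "rae_pct"] = relative_agronomic_efficiency(
                    r["recovery_pct"], ref_recovery
                )

    summary = summarize_partition(results, exclude_flagged=exclude_flagged)
    return results, summary


def summarize_partition(results: pd.DataFrame, *, exclude_flagged: bool = True) -> pd.DataFrame:
    """Treatment x soil means, SDs and counts of the partition columns."""
    df = results
    if exclude_flagged:
        df = df[~df["flags"].apply(lambda s: bool(set(s) & F.EXCLUDING_FLAGS))]
    value_cols = [
        "uptake",
        "pdf_fertilizer",
        "pdf_soil",
        "pdf_seed",
        "pdf_fertilizer_pct",
        "recovery_pct",
        "rae_pct",
    ]
    out = []
    for (soil, treatment), g in df.groupby(["soil", "treatment"], sort=False):
        rec = {"soil": soil, "treatment": treatment, "n": len(g)}
        for c in value_cols:
            rec[f"{c}_mean"] = float(g[c].mean())
            rec[f"{c}_sd"] = float(g[c].std(ddof=1)) if len(g) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out)
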