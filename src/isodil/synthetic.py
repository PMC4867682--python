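"""Synthetic datasets with embedded ground truth.

Every generator returns a table shaped like the corresponding input CSV
plus a truth object sufficient to recompute the expected pipeline output
in closed form, so parameter-recovery and round-trip tests need no
external data.  All randomness flows through a single integer seed; the
noise model is multiplicative Gaussian (truncated at zero) with a
per-quantity coefficient of variation.

Default design constants mirror the emulated study: dose 30 mg P per kg
soil, soil labeling 1.1 MBq per kg, direct-labeled mineral P at
40 kBq per mg, kinetics sampling at 1-90 min, solution:soil ratio 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .errors import InvalidParameterError
from .kinetics import KineticsSeries, predict_r_ratio
from .partition import SeedPModel
from .tracer import P33_HALF_LIFE_DAYS, decay_factor

__all__ = [
    "TreatmentTruth",
    "SyntheticTruth",
    "default_truth",
    "simulate_seed_experiment",
    "simulate_pot_experiment",
    "simulate_kinetics_series",
    "simulate_incubation",
]


@dataclass(frozen=True)
class TreatmentTruth:
    """True generating parameters for one treatment on one soil."""

    uptake_mean: float  # mg P per kg soil
    fert_share: float  # fraction of uptake from fertilizer, in [0, 1]
    labeling: str = "indirect"  # direct | indirect
    dose: float = datasets.DOSE_MG_P_PER_KG
    sa_fert: float = float("nan")  # Bq per mg P, direct labeling only

    def __post_init__(self):
        if not (0 <= self.fert_share <= 1):
            raise InvalidParameterError(f"fert_share must be in [0,1], got {self.fert_share}")
        if self.uptake_mean <= 0:
            raise InvalidParameterError("uptake_mean must be > 0")


@dataclass(frozen=True)
class PoolTruth:
    """True incubation pool values for one treatment x soil x day."""

    resin_p: float
    pdff_pct: float
    pmic: float


@dataclass
class SyntheticTruth:
    """Ground truth embedded in a generated dataset."""

    seed_model: SeedPModel
    treatments: dict  # (treatment, soil) -> TreatmentTruth
    sa_soil: dict = field(default_factory=dict)  # soil -> Bq per mg P
    pools: dict = field(default_factory=dict)  # (treatment, soil, day) -> PoolTruth
    kinetics: dict = field(default_factory=dict)  # sample_id -> (m, n, c_p, pi_total)
    noise_cv: dict = field(default_factory=dict)
    rng_seed: int = 0

    def true_recovery_pct(self, treatment: str, soil: str) -> float:
        t = self.treatments[(treatment, soil)]
        return t.fert_share * t.uptake_mean / t.dose * 100.0


_DEFAULT_SHARES = {
    # patterned on realistic magnitudes; synthetic, not measured values
    "NoP": (6.0, 0.0),
    "MinP": (10.2, 0.42),
    "Manure": (7.0, 0.40),
    "FishSludge": (7.5, 0.29),
    "MeatBoneMeal": (6.4, 0.11),
    "WoodAsh": (7.1, 0.24),
    "MinPdir": (10.3, 0.37),
}


def default_truth(
    soils=("unlimed", "limed"),
    seed_model: SeedPModel = SeedPModel(a=0.04, b=0.5),
    seed: int = 0,
) -> SyntheticTruth:
    """Truth object for the default 2-soil x 7-treatment pot design."""
    treatments = {}
    for soil in soils:
        for name, (uptake, share) in _DEFAULT_SHARES.items():
            labeling = "direct" if name == "MinPdir" else "indirect"
            sa_fert = datasets.SA_MINPDIR if labeling == "direct" else float("nan")
            treatments[(name, soil)] = TreatmentTruth(
                uptake_mean=uptake,
                fert_share=share,
                labeling=labeling,
                dose=datasets.DOSE_MG_P_PER_KG,
                sa_fert=sa_fert,
            )
    sa_soil = {soil: 200.0 - 20.0 * i for i, soil in enumerate(soils)}
    return SyntheticTruth(
        seed_model=seed_model,
        treatments=treatments,
        sa_soil=sa_soil,
        noise_cv={"p": 0.05, "activity": 0.02},
        rng_seed=seed,
    )


def _mult_noise(rng, cv, size=None):
    """Multiplicative Gaussian factor truncated at zero."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    draw = rng.normal(1.0, cv, size=size)
    return np.abs(draw)


def simulate_seed_experiment(
    rates=(0.0, 7.5, 15.0, 22.5, 30.0),
    seed_p_total: float = 0.71,
    a: float = 0.04,
    b: float = 0.5,
    noise_cv: float = 0.0,
    seed: int = 0,
    replicates: int = 4,
    activity_per_pot: float = 720e3,
):
    """Direct-labeled sand-culture experiment isolating the seed source.

    Per pot, uptake grows with the fertilization rate, the true
    seed-derived P follows the linear rule ``a * uptake + b``, and the
    rest of the uptake carries the fertilizer label.  The reported
    ``pdf_seed`` column is recomputed from the (noisy) activity through
    the direct-labeling equations, exactly as a real experiment would.

    Returns (table, SyntheticTruth).
    """
    rates = list(rates)
    if not rates:
        raise InvalidParameterError("rates must be non-empty")
    if seed_p_total <= 0:
        raise InvalidParameterError("seed_p_total must be > 0")
    rng = np.random.default_rng(seed)
    # at rate 0 all shoot P is seed-derived, so the unfertilized uptake
    # must sit on the fixed point of the seed line (u = b / (1 - a))
    u0 = b / (1.0 - a)
    rows = []
    for rate in rates:
        sa_fert = activity_per_pot / rate if rate > 0 else np.nan
        for rep in range(1, replicates + 1):
            uptake_true = (u0 + 0.016 * rate) * _mult_noise(rng, noise_cv)
            seed_true = min(a * uptake_true + b, uptake_true)
            fert_true = uptake_true - seed_true
            if rate > 0:
                activity = sa_fert * fert_true * _mult_noise(rng, noise_cv)
                pdf_fert_est = activity / sa_fert
                pdf_seed_est = uptake_true - pdf_fert_est
            else:
                activity = 0.0
                pdf_seed_est = uptake_true
            rows.append(
                {
                    "rate": rate,
                    "replicate": rep,
                    "uptake": uptake_true,
                    "activity_bq": activity,
                    "sa_fert": sa_fert,
                    "pdf_seed": pdf_seed_est,
                }
            )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed_model=SeedPModel(a=a, b=b),
        treatments={},
        noise_cv={"p": noise_cv, "activity": noise_cv},
        rng_seed=seed,
    )
    return table, truth


def simulate_pot_experiment(
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    replicates: int = 4,
    noise_cv_p: float | None = None,
    noise_cv_activity: float | None = None,
    half_life_days: float = P33_HALF_LIFE_DAYS,
    count_day_range=(44.0, 60.0),
):
    """Pot experiment emulation with a consistent isotope mixing model.

    Indirect pots carry label only in their soil-derived P (activity =
    SA_soil * pdf_soil); direct pots only in their fertilizer-derived P.
    Emitted activities are decay-*uncorrected* with count dates (days
    since labeling) so ingestion exercises the decay correction.

    Returns (plants table, fertilizers table, SyntheticTruth).
    """
    if truth is None:
        truth = default_truth(seed=seed)
    if noise_cv_p is None:
        noise_cv_p = truth.noise_cv.get("p", 0.05)
    if noise_cv_activity is None:
        noise_cv_activity = truth.noise_cv.get("activity", 0.02)
    rng = np.random.default_rng(seed)
    model = truth.seed_model

    rows = []
    for (name, soil), t in truth.treatments.items():
        if soil not in truth.sa_soil:
            raise InvalidParameterError(f"truth lacks a soil SA for {soil!r}")
        for rep in range(1, replicates + 1):
            uptake = t.uptake_mean * _mult_noise(rng, noise_cv_p)
            seed_p = max(model.a * uptake + model.b, 0.0)
            fert_p = t.fert_share * uptake
            soil_p = uptake - fert_p - seed_p
            if soil_p < 0:
                raise InvalidParameterError(
                    f"{name}/{soil}: shares exceed uptake (soil P {soil_p:.3f})"
                )
            if t.labeling == "direct":
                activity = t.sa_fert * fert_p
            else:
                activity = truth.sa_soil[soil] * soil_p
            activity *= _mult_noise(rng, noise_cv_activity)
            count_day = rng.uniform(*count_day_range)
            raw_activity = activity / decay_factor(count_day, half_life_days)
            p_conc = 1.9 * _mult_noise(rng, noise_cv_p)
            rows.append(
                {
                    "treatment": name,
                    "soil": soil,
                    "replicate": rep,
                    "labeling": t.labeling,
                    "dm_g_per_kg": uptake / p_conc,
                    "p_conc_mg_per_g": p_conc,
                    "activity_bq": raw_activity,
                    "count_date": count_day,
                }
            )
    plants = pd.DataFrame(rows)

    ferts = datasets.fertilizer_products()
    seen = {name for (name, _s) in truth.treatments}
    ferts = ferts[ferts["name"].isin(seen)].reset_index(drop=True)
    return plants, ferts, truth


def simulate_kinetics_series(
    m: float,
    n: float,
    c_p: float,
    pi_total: float,
    times=datasets.KINETICS_TIMES,
    noise_cv: float = 0.0,
    seed: int = 0,
    r_injected: float = 750.0,
    ratio: float = datasets.SOLUTION_SOIL_RATIO,
    sample_id: str = "sim",
    max_retries: int = 100,
) -> KineticsSeries:
    """Forward-simulated exchange-kinetics series.

    Evaluates the dilution model at the sampling times, scales by the
    injected activity, and applies multiplicative noise; draws violating
    the series invariants (r_t <= R, positivity) are resampled up to
    ``max_retries`` times per point.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("times must be non-empty")
    rng = np.random.default_rng(seed)
    ideal = predict_r_ratio(times, m, n, c_p, pi_total, ratio) * r_injected
    r_t = np.empty_like(ideal)
    for i, v in enumerate(ideal):
        for _ in range(max_retries):
            cand = v * _mult_noise(rng, noise_cv)
            if 0 < cand <= r_injected:
                r_t[i] = cand
                break
        else:
            raise InvalidParameterError(
                "could not draw an admissible r_t; noise_cv too large"
            )
    return KineticsSeries(
        sample_id=sample_id,
        times=times,
        r_t=r_t,
        r_injected=r_injected,
        c_p=c_p,
        pi_total=pi_total,
        ratio=ratio,
    )


def default_pool_truth(soils=("unlimed", "limed"), days=(7, 21)) -> dict:
    """Plausible synthetic pool truths per treatment x soil x day."""
    base = {
        "NoP": (11.0, 0.0, 5.0),
        "MinP": (23.0, 45.0, 4.0),
        "Manure": (18.0, 38.0, 10.0),
        "FishSludge": (15.0, 28.0, 7.0),
        "MeatBoneMeal": (12.0, 16.0, 8.0),
        "WoodAsh": (14.5, 41.0, 7.5),
    }
    pools = {}
    for soil in soils:
        bump = 0.0 if soil == "unlimed" else 2.0
        for day in days:
            drop = 0.0 if day == 7 else 4.0
            for name, (resin, pdff, pmic) in base.items():
                pools[(name, soil, day)] = PoolTruth(
                    resin_p=max(resin - drop, 1.0), pdff_pct=pdff, pmic=pmic + bump
                )
    return pools


def simulate_incubation(
    pool_truth: dict | None = None,
    sa_extract: dict | None = None,
    seed: int = 0,
    replicates: int = 4,
    noise_cv: float = 0.0,
    nop_treatment: str = "NoP",
):
    """Extraction records (fumigated/non-fumigated pairs) with known truth.

    ``pool_truth`` maps (treatment, soil, day) to PoolTruth;
    ``sa_extract`` maps soil to the reference extract SA (Bq per mg P).
    Returns (table, SyntheticTruth).
    """
    if pool_truth is None:
        pool_truth = default_pool_truth()
    soils = {s for (_t, s, _d) in pool_truth}
    if sa_extract is None:
        sa_extract = {soil: 500.0 for soil in soils}
    if not any(t == nop_treatment for (t, _s, _d) in pool_truth):
        raise InvalidParameterError(f"pool truth lacks the {nop_treatment!r} reference")
    rng = np.random.default_rng(seed)
    rows = []
    for (treatment, soil, day), pt in pool_truth.items():
        sa_ref = sa_extract[soil]
        sa = sa_ref * (1.0 - pt.pdff_pct / 100.0)
        for rep in range(1, replicates + 1):
            resin = pt.resin_p * _mult_noise(rng, noise_cv)
            activity = sa * resin * _mult_noise(rng, noise_cv)
            fum = (pt.resin_p + pt.pmic) * _mult_noise(rng, noise_cv)
            base_id = f"{treatment}-{soil}-d{day}-r{rep}"
            rows.append(
                {
                    "sample_id": base_id,
                    "treatment": treatment,
                    "soil": soil,
                    "replicate": rep,
                    "day": day,
                    "fumigated": False,
                    "extract_p": resin,
                    "extract_activity": activity,
                }
            )
            rows.append(
                {
                    "sample_id": base_id + "-fum",
                    "treatment": treatment,
                    "soil": soil,
                    "replicate": rep,
                    "day": day,
                    "fumigated": True,
                    "extract_p": fum,
                    "extract_activity": activity,
                }
            )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed_model=SeedPModel(a=0.0, b=0.0),
        treatments={},
        pools=dict(pool_truth),
        sa_soil=dict(sa_extract),
        noise_cv={"pool": noise_cv},
        rng_seed=seed,
    )
    return table, truth
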