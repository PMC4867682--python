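import numpy as np
import pandas as pd
import pytest

from isodil import flags as F
from isodil.errors import (
    DegenerateFitError,
    DegenerateReferenceError,
    InvalidParameterError,
)
from isodil.partition import (
    SeedPModel,
    fertilizer_recovery,
    fit_seed_model,
    ols_fit,
    partition_experiment,
    pdf_fertilizer_direct,
    pdf_fertilizer_indirect,
    pdf_soil_indirect,
    predict_seed_p,
    relative_agronomic_efficiency,
    sa_noP_reference,
    seed_p_applied,
)


class TestSeedModel:
    def test_exact_line(self):
        uptake = np.array([2.0, 4.0, 6.0, 8.0])
        m = fit_seed_model(uptake, 0.05 * uptake + 0.4)
        assert m.a == pytest.approx(0.05, abs=1e-12)
        assert m.b == pytest.approx(0.4, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)
        assert m.n_points == 4

    def test_collinear_third_point(self):
        x = np.array([1.0, 3.0, 2.0])
        y = 0.1 * x + 0.2
        m = fit_seed_model(x, y)
        assert m.a == pytest.approx(0.1, abs=1e-12)
        assert m.b == pytest.approx(0.2, abs=1e-12)

    def test_noisy_recovery_against_normal_equations(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(4, 12, 20)
        y = 0.04 * x + 0.5 + rng.normal(0, 0.05, 20)
        m = fit_seed_model(x, y)
        # closed-form normal-equations oracle
        a_hat = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        b_hat = y.mean() - a_hat * x.mean()
        assert m.a == pytest.approx(a_hat, rel=1e-10)
        assert m.b == pytest.approx(b_hat, rel=1e-10)
        assert abs(m.a - 0.04) < 0.02

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError):
            fit_seed_model([1.0, 2.0], [0.1, 0.2])

    def test_zero_variance(self):
        with pytest.raises(DegenerateFitError):
            fit_seed_model([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])


class TestPredictSeedP:
    def test_zero_slope(self):
        assert predict_seed_p(10.0, SeedPModel(a=0.0, b=0.7)).value == pytest.approx(0.7)

    def test_arithmetic(self):
        assert predict_seed_p(10.0, SeedPModel(a=0.05, b=0.4)).value == pytest.approx(0.9)

    def test_clamped_at_zero(self):
        pred = predict_seed_p(0.0, SeedPModel(a=0.05, b=-0.1))
        assert pred.value == 0.0
        assert pred.clamped

    def test_negative_uptake_rejected(self):
        with pytest.raises(InvalidParameterError):
            predict_seed_p(-1.0, SeedPModel(a=0.05, b=0.4))


class TestSeedPApplied:
    def test_five_seed_input(self):
        assert seed_p_applied(0.20, 3.49) == pytest.approx(0.698)


class TestDirectPartition:
    def test_unlabeled_plant(self):
        assert pdf_fertilizer_direct(0.0, 100.0, 10.0).value == 0.0

    def test_ratio_one_gives_full_uptake(self):
        fv = pdf_fertilizer_direct(100.0, 100.0, 10.0)
        assert fv.value == pytest.approx(10.0)
        assert not fv.flags

    def test_printed_row(self):
        # SA ratio 0.369 at uptake 10.3 gives 12.7% recovery at dose 30
        fv = pdf_fertilizer_direct(0.369 * 40_000, 40_000.0, 10.3)
        assert fv.value == pytest.approx(3.80, abs=0.005)
        assert fertilizer_recovery(fv.value, 30.0) == pytest.approx(12.7, abs=0.05)

    def test_impossible_ratio_flagged(self):
        fv = pdf_fertilizer_direct(110.0, 100.0, 10.0)
        assert F.IMPOSSIBLE_RATIO in fv.flags

    def test_monotone_in_sa_plant(self):
        vals = [pdf_fertilizer_direct(sa, 100.0, 10.0).value for sa in (10, 20, 50, 99)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_sa_fert(self):
        with pytest.raises(InvalidParameterError):
            pdf_fertilizer_direct(10.0, 0.0, 10.0)


class TestNoPReference:
    def test_single_pot_arithmetic(self, seed_model):
        rec = pd.DataFrame({"uptake": [6.0], "activity": [600.0]})
        model = SeedPModel(a=0.0, b=0.6)
        assert sa_noP_reference(rec, model) == pytest.approx(600.0 / 5.4, rel=1e-12)

    def test_no_seed_limit(self):
        rec = pd.DataFrame({"uptake": [6.0], "activity": [600.0]})
        assert sa_noP_reference(rec, SeedPModel(a=0.0, b=0.0)) == pytest.approx(100.0)

    def test_mean_idempotent(self):
        rec = pd.DataFrame({"uptake": [6.0, 6.0], "activity": [600.0, 600.0]})
        single = pd.DataFrame({"uptake": [6.0], "activity": [600.0]})
        model = SeedPModel(a=0.0, b=0.6)
        assert sa_noP_reference(rec, model) == sa_noP_reference(single, model)

    def test_degenerate_reference(self):
        rec = pd.DataFrame({"uptake": [0.5], "activity": [600.0]})
        with pytest.raises(DegenerateReferenceError):
            sa_noP_reference(rec, SeedPModel(a=0.0, b=0.6))


class TestIndirectPartition:
    def test_ratio_one(self):
        assert pdf_soil_indirect(100.0, 100.0, 10.0, 0.9) == pytest.approx(9.1)

    def test_zero_sa_plant(self):
        assert pdf_soil_indirect(0.0, 100.0, 10.0, 0.9) == 0.0

    def test_arithmetic(self):
        assert pdf_soil_indirect(55.0, 100.0, 10.2, 0.95) == pytest.approx(0.55 * 9.25)

    def test_invalid_reference(self):
        with pytest.raises(InvalidParameterError):
            pdf_soil_indirect(55.0, 0.0, 10.2, 0.95)

    def test_fert_by_difference(self):
        fv = pdf_fertilizer_indirect(10.2, 5.0875, 0.95)
        assert fv.value == pytest.approx(4.1625)
        assert not fv.flags

    def test_mass_balance_boundary(self):
        assert pdf_fertilizer_indirect(10.0, 9.3, 0.7).value == pytest.approx(0.0, abs=1e-12)

    def test_negative_flagged_not_raised(self):
        fv = pdf_fertilizer_indirect(6.0, 5.5, 0.7)
        assert fv.value == pytest.approx(-0.2)
        assert F.NEGATIVE_PDF_FERTILIZER in fv.flags


class TestRecoveryAndRAE:
    def test_zero(self):
        assert fertilizer_recovery(0.0, 30.0) == 0.0

    def test_printed_minp_cell(self):
        assert fertilizer_recovery(0.424 * 10.2, 30.0) == pytest.approx(14.4, abs=0.05)

    def test_invalid_dose(self):
        with pytest.raises(InvalidParameterError):
            fertilizer_recovery(1.0, 0.0)

    def test_rae_identity(self):
        assert relative_agronomic_efficiency(14.4, 14.4) == pytest.approx(100.0)

    def test_rae_printed_cells(self):
        assert relative_agronomic_efficiency(2.3, 14.4) == pytest.approx(16.0, abs=0.5)
        assert relative_agronomic_efficiency(10.7, 16.3) == pytest.approx(65.7, abs=0.5)

    def test_invalid_reference(self):
        with pytest.raises(InvalidParameterError):
            relative_agronomic_efficiency(5.0, 0.0)


class TestOLS:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = ols_fit(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_constant_y(self):
        res = ols_fit(np.arange(5.0), np.ones(5))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_against_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = ols_fit(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        a = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        b = y.mean() - a * x.mean()
        assert res.slope == pytest.approx(a, rel=1e-10)
        assert res.intercept == pytest.approx(b, rel=1e-10)

    def test_degenerate_x(self):
        with pytest.raises(DegenerateFitError):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartitionExperiment:
    def test_zero_noise_recovers_truth(self, noiseless_pot):
        plants, ferts, truth = noiseless_pot
        plants = _corrected(plants)
        results, summary = partition_experiment(plants, ferts, truth.seed_model)
        for (t, s), tt in truth.treatments.items():
            row = summary[(summary.treatment == t) & (summary.soil == s)].iloc[0]
            assert row["pdf_fertilizer_pct_mean"] == pytest.approx(
                tt.fert_share * 100, abs=1e-8
            )

    def test_mass_balance_exact(self, noisy_pot):
        plants, ferts, truth = noisy_pot
        results, _ = partition_experiment(_corrected(plants), ferts, truth.seed_model)
        indirect = results[results.labeling == "indirect"]
        balance = indirect.pdf_fertilizer + indirect.pdf_soil + indirect.pdf_seed
        assert np.allclose(balance, indirect.uptake, rtol=0, atol=1e-12)

    def test_rae_of_reference_is_100(self, noisy_pot):
        plants, ferts, truth = noisy_pot
        _, summary = partition_experiment(_corrected(plants), ferts, truth.seed_model)
        minp = summary[summary.treatment == "MinP"]
        assert (minp["rae_pct_mean"] == 100.0).all()

    def test_missing_nop_reference_raises(self, noiseless_pot):
        plants, ferts, truth = noiseless_pot
        plants = _corrected(plants)
        plants = plants[plants.treatment != "NoP"]
        from isodil.errors import MissingReferenceError

        with pytest.raises(MissingReferenceError):
            partition_experiment(plants, ferts, truth.seed_model)

    def test_flagged_pot_excluded_from_summary(self, noiseless_pot):
        plants, ferts, truth = noiseless_pot
        plants = _corrected(plants)
        # force one MeatBoneMeal pot to carry more activity than the
        # reference allows, driving its fertilizer P negative
        mask = (
            (plants.treatment == "MeatBoneMeal")
            & (plants.soil == "unlimed")
            & (plants.replicate == 1)
        )
        plants.loc[mask, "activity"] *= 1.5
        results, summary = partition_experiment(
            plants, ferts, truth.seed_model, exclude_flagged=True
        )
        flagged = results[results["flags"].apply(lambda s: "NEGATIVE_PDF_FERTILIZER" in s)]
        assert len(flagged) == 1
        row = summary[(summary.treatment == "MeatBoneMeal") & (summary.soil == "unlimed")]
        assert int(row["n"].iloc[0]) == 3


def _corrected(plants):
    """Apply ingestion arithmetic (decay correction + uptake) in-place."""
    from isodil.tracer import decay_factor

    plants = plants.copy()
    plants["activity"] = plants["activity_bq"] * plants["count_date"].map(
        lambda d: decay_factor(d)
    )
    plants["uptake"] = plants["dm_g_per_kg"] * plants["p_conc_mg_per_g"]
    return plants
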