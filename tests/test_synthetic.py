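import numpy as np
import pandas as pd
import pytest

from isodil.errors import InvalidParameterError
from isodil.kinetics import e_value_1min, fit_kinetics
from isodil.partition import fit_seed_model, partition_experiment
from isodil.synthetic import (
    default_truth,
    simulate_incubation,
    simulate_kinetics_series,
    simulate_pot_experiment,
    simulate_seed_experiment,
)
from isodil.tracer import decay_factor


def _ingest(plants):
    plants = plants.copy()
    plants["activity"] = plants["activity_bq"] * plants["count_date"].map(decay_factor)
    plants["uptake"] = plants["dm_g_per_kg"] * plants["p_conc_mg_per_g"]
    return plants


class TestSeedExperiment:
    def test_zero_noise_round_trip(self):
        tab, truth = simulate_seed_experiment(a=0.04, b=0.5, noise_cv=0.0, seed=0)
        model = fit_seed_model(tab.uptake, tab.pdf_seed)
        assert model.a == pytest.approx(0.04, abs=1e-9)
        assert model.b == pytest.approx(0.5, abs=1e-9)

    def test_determinism(self):
        t1, _ = simulate_seed_experiment(noise_cv=0.05, seed=42)
        t2, _ = simulate_seed_experiment(noise_cv=0.05, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_seed_experiment(rates=[])

    def test_slope_estimator_nearly_unbiased(self):
        slopes = []
        for seed in range(500):
            tab, _ = simulate_seed_experiment(noise_cv=0.05, seed=seed)
            slopes.append(fit_seed_model(tab.uptake, tab.pdf_seed).a)
        assert abs(np.mean(slopes) - 0.04) < 0.05 * 0.04


class TestPotExperiment:
    def test_zero_noise_partition_recovers_truth(self, noiseless_pot):
        plants, ferts, truth = noiseless_pot
        _, summary = partition_experiment(_ingest(plants), ferts, truth.seed_model)
        for (t, s), tt in truth.treatments.items():
            row = summary[(summary.treatment == t) & (summary.soil == s)].iloc[0]
            assert row["pdf_fertilizer_pct_mean"] == pytest.approx(
                100 * tt.fert_share, abs=1e-8
            )

    def test_direct_indirect_equivalence_zero_noise(self):
        # same generating truth run through both labeling routes
        truth = default_truth(seed=0)
        plants, ferts, truth = simulate_pot_experiment(
            truth, seed=0, noise_cv_p=0.0, noise_cv_activity=0.0
        )
        plants = _ingest(plants)
        results, _ = partition_experiment(plants, ferts, truth.seed_model)
        minp = results[(results.treatment == "MinP") & (results.soil == "unlimed")]
        # MinP and MinPdir embed shares 0.42 / 0.37; normalise per uptake
        share_indirect = (minp.pdf_fertilizer / minp.uptake).to_numpy()
        assert np.allclose(share_indirect, 0.42, atol=1e-9)
        mdir = results[(results.treatment == "MinPdir") & (results.soil == "unlimed")]
        share_direct = (mdir.pdf_fertilizer / mdir.uptake).to_numpy()
        assert np.allclose(share_direct, 0.37, atol=1e-9)

    def test_recovery_within_3_points_at_default_cv(self):
        truth = default_truth(seed=5)
        plants, ferts, truth = simulate_pot_experiment(
            truth, seed=5, noise_cv_p=0.05, noise_cv_activity=0.02
        )
        _, summary = partition_experiment(_ingest(plants), ferts, truth.seed_model)
        for (t, s), tt in truth.treatments.items():
            if tt.fert_share == 0:
                continue
            row = summary[(summary.treatment == t) & (summary.soil == s)].iloc[0]
            assert abs(row["recovery_pct_mean"] - truth.true_recovery_pct(t, s)) < 3.0

    def test_emitted_activities_are_decay_uncorrected(self, noiseless_pot):
        plants, _, truth = noiseless_pot
        assert (plants["count_date"] > 0).all()

    def test_determinism(self):
        truth = default_truth(seed=9)
        p1, f1, _ = simulate_pot_experiment(truth, seed=9)
        p2, f2, _ = simulate_pot_experiment(truth, seed=9)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(f1, f2)


class TestKineticsSimulation:
    def test_zero_noise_round_trip(self):
        s = simulate_kinetics_series(0.27, 0.40, 0.09, 568.0, noise_cv=0.0)
        fit = fit_kinetics(s)
        assert fit.m == pytest.approx(0.27, abs=1e-6)
        assert fit.n == pytest.approx(0.40, abs=1e-6)

    def test_e_value_oracle(self):
        s = simulate_kinetics_series(0.27, 0.40, 0.09, 568.0, noise_cv=0.0)
        e = e_value_1min(s.c_p, s.r_injected, float(s.r_t[0]), s.ratio)
        assert e == pytest.approx(3.3632, abs=0.001)

    def test_noisy_e_value_centered(self):
        ref = 3.3632
        es = []
        for seed in range(200):
            s = simulate_kinetics_series(0.27, 0.40, 0.09, 568.0, noise_cv=0.02, seed=seed)
            es.append(e_value_1min(s.c_p, s.r_injected, float(s.r_t[0]), s.ratio))
        assert abs(np.mean(es) - ref) / ref < 0.01

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_kinetics_series(1.5, 0.4, 0.1, 568.0)

    def test_determinism(self):
        s1 = simulate_kinetics_series(0.3, 0.4, 0.1, 568.0, noise_cv=0.02, seed=7)
        s2 = simulate_kinetics_series(0.3, 0.4, 0.1, 568.0, noise_cv=0.02, seed=7)
        assert np.array_equal(s1.r_t, s2.r_t)


class TestIncubationSimulation:
    def test_zero_pmic_means_equal_extracts(self):
        from isodil.synthetic import PoolTruth

        truth = {("NoP", "unlimed", 7): PoolTruth(10.0, 0.0, 0.0)}
        table, _ = simulate_incubation(truth, noise_cv=0.0)
        plain = table[~table.fumigated].extract_p.to_numpy()
        fum = table[table.fumigated].extract_p.to_numpy()
        assert np.allclose(plain, fum)

    def test_missing_nop_rejected(self):
        from isodil.synthetic import PoolTruth

        truth = {("MinP", "unlimed", 7): PoolTruth(20.0, 40.0, 4.0)}
        with pytest.raises(InvalidParameterError):
            simulate_incubation(truth)

    def test_noise_scaling_with_replicates(self):
        # estimator spread shrinks roughly as 1/sqrt(replicates)
        def spread(replicates):
            devs = []
            for seed in range(60):
                table, truth = simulate_incubation(
                    noise_cv=0.1, seed=seed, replicates=replicates
                )
                sub = table[
                    (table.treatment == "MinP")
                    & (table.soil == "unlimed")
                    & (table.day == 7)
                    & (~table.fumigated)
                ]
                devs.append(sub.extract_p.mean() - truth.pools[("MinP", "unlimed", 7)].resin_p)
            return np.std(devs)

        s4, s16 = spread(4), spread(16)
        assert s16 < s4 / 1.4
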