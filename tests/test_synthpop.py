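"""Roster generation, forward model, and generator calibration."""

import numpy as np
import pandas as pd
import pytest

from pkherit import (
    ConfigurationError,
    PopulationConfig,
    TruthParams,
    nca_table,
    parent_curve,
    simulate_dataset,
    simulate_effects,
    simulate_roster,
    simulate_study,
)


class TestRoster:
    def test_default_design(self):
        roster = simulate_roster(PopulationConfig(seed=3))
        assert len(roster) == 198
        assert roster["breed"].nunique() == 4
        assert roster["sire_id"].nunique() == 20
        counts = roster.groupby("sire_id").size()
        assert counts.between(4, 24).all()
        assert roster["batch"].nunique() == 9
        # each sire maps to exactly one breed
        assert (roster.groupby("sire_id")["breed"].nunique() == 1).all()

    def test_degenerate_single_sire(self):
        cfg = PopulationConfig(n_batches=1, sires_per_breed={"Duroc": 1},
                               progeny_range=(1, 10), n_animals=4)
        roster = simulate_roster(cfg)
        assert len(roster) == 4
        assert roster["sire_id"].nunique() == 1

    def test_seeded_determinism(self):
        a = simulate_roster(PopulationConfig(seed=5))
        b = simulate_roster(PopulationConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_roster(PopulationConfig(seed=6))
        assert not a.equals(c)

    def test_infeasible_config_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_roster(PopulationConfig(n_animals=500))  # 20 sires x 24 max
        with pytest.raises(ConfigurationError):
            simulate_roster(PopulationConfig(n_animals=30))  # below 20 x 4 min

    def test_drug_assignment_balanced(self):
        roster = simulate_roster(PopulationConfig(seed=1))
        by_drug = roster.groupby("drug").size()
        assert abs(by_drug["FBZ"] - by_drug["FLU"]) <= 12  # near-balance overall
        # within batch x breed x sex blocks the split is off by at most 1
        for _, grp in roster.groupby(["batch", "breed", "sex"]):
            n_fbz = (grp["drug"] == "FBZ").sum()
            assert abs(n_fbz - (len(grp) - n_fbz)) <= 1


class TestEffects:
    def test_zero_sire_variance_gives_zero_deviations(self):
        roster = simulate_roster(PopulationConfig(seed=2))
        truth = TruthParams(sigma2_sire={"log_scale": 0.0},
                            sigma2_batch={"log_scale": 0.0},
                            sigma2_e={"log_scale": 0.0},
                            fixed_sex={}, fixed_breed={})
        eff = simulate_effects(roster, truth, seed=2)
        assert np.allclose(eff["log_scale"], 0.0)
        assert np.allclose(eff["log_rate"], 0.0)

    def test_within_sire_equality_when_only_sire_varies(self):
        cfg = PopulationConfig(n_batches=1, sires_per_breed={"Duroc": 3},
                               progeny_range=(4, 4), n_animals=12, sex_ratio=0.0)
        roster = simulate_roster(cfg)
        truth = TruthParams(sigma2_sire={"log_scale": 0.3},
                            sigma2_batch={"log_scale": 0.0},
                            sigma2_e={"log_scale": 0.0})
        eff = simulate_effects(roster, truth, seed=4).set_index("animal_id")
        merged = roster.join(eff, on="animal_id")
        assert (merged.groupby("sire_id")["log_scale"].nunique() == 1).all()

    def test_law_of_total_variance(self):
        """Variance of half-sib family means -> sigma2_sire + sigma2_e/n."""
        cfg = PopulationConfig(n_batches=10, sires_per_breed={"Duroc": 500},
                               progeny_range=(20, 20), n_animals=10000)
        roster = simulate_roster(cfg)
        truth = TruthParams(sigma2_sire={"log_scale": 0.05},
                            sigma2_batch={"log_scale": 0.0},
                            sigma2_e={"log_scale": 0.04},
                            fixed_sex={}, fixed_breed={})
        eff = simulate_effects(roster, truth, seed=9).set_index("animal_id")
        merged = roster.join(eff, on="animal_id")
        fam_var = merged.groupby("sire_id")["log_scale"].mean().var(ddof=1)
        expected = 0.05 + 0.04 / 20
        assert fam_var == pytest.approx(expected, rel=0.10)


class TestDataset:
    def test_noise_free_curve_is_exact_biexponential(self):
        cfg = PopulationConfig(n_batches=1, sires_per_breed={"Duroc": 1},
                               progeny_range=(1, 1), n_animals=1, sex_ratio=0.0)
        roster = simulate_roster(cfg)
        truth = TruthParams(sigma2_sire={}, sigma2_batch={}, sigma2_e={},
                            fixed_sex={}, fixed_breed={}, cv_measurement=0.0,
                            loq_ug_per_ml=0.0)
        data = simulate_dataset(roster, truth, cfg)
        drug = roster["drug"].iloc[0]
        par = data[data["compound"] == "parent"]
        curve = truth.pop_curve[drug]
        expected = parent_curve(curve, roster["dose_mg_per_kg"].iloc[0],
                                par["time_h"].to_numpy())
        assert np.allclose(par["conc_ug_per_ml"].to_numpy(), expected, atol=1e-12)

    def test_flu_population_clearance_matches_observed_study_mean(self):
        """Default truth is calibrated to the observed FLU parent clearance
        0.12 +/- 0.04 L/h/kg."""
        _, _, data = simulate_study(seed=21)
        pk = nca_table(data)
        cl = pk[(pk["drug"] == "FLU") & (pk["compound"] == "parent")
                ]["Cl_L_per_h_per_kg"].mean()
        assert 0.08 <= cl <= 0.16

    def test_dataset_determinism_and_seed_sensitivity(self):
        _, _, a = simulate_study(seed=3)
        _, _, b = simulate_study(seed=3)
        pd.testing.assert_frame_equal(a, b)
        _, _, c = simulate_study(seed=4)
        assert not a["conc_ug_per_ml"].equals(c["conc_ug_per_ml"])

    def test_ar1_measurement_noise_autocorrelation(self):
        """Pooled lag-1 autocorrelation of log measurement residuals
        recovers the generating rho = 0.6 within +/- 0.05."""
        cfg = PopulationConfig(
            n_batches=4, sires_per_breed={"Duroc": 100},
            progeny_range=(20, 20), n_animals=2000, drugs=("FLU",),
            dose_mg_per_kg={"FLU": 3.0},
            schedule_h={"FLU": [0.0, 0.5, 1, 2, 3, 4, 8, 12, 24, 48]},
        )
        roster = simulate_roster(cfg)
        truth = TruthParams(sigma2_sire={}, sigma2_batch={}, sigma2_e={},
                            fixed_sex={}, fixed_breed={},
                            cv_measurement=0.20, ar1_rho={"FLU": 0.6},
                            loq_ug_per_ml=0.0)
        data = simulate_dataset(roster, truth, cfg, seed=13)
        par = data[data["compound"] == "parent"]
        curve = truth.pop_curve["FLU"]
        clean = parent_curve(curve, 3.0, par["time_h"].to_numpy())
        z = np.log(par["conc_ug_per_ml"].to_numpy() / clean)
        z = z.reshape(-1, 10)  # animals x sampling index
        z0, z1 = z[:, :-1].ravel(), z[:, 1:].ravel()
        r = np.corrcoef(z0, z1)[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_bloq_recorded_missing(self):
        _, _, data = simulate_study(seed=5)
        post = data[data["time_h"] > 0]
        assert post["conc_ug_per_ml"].isna().any()
        assert (post["conc_ug_per_ml"].dropna() >= 0).all()
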