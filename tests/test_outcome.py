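import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from adjiv._errors import ConfigurationError, DegenerateInputError
from adjiv.cohort import CovariateMarginals, CovariateTable, generate_covariates
from adjiv.hospitals import HospitalConfig, HospitalTable, draw_hospitals
from adjiv.outcome import (
    SCENARIOS,
    CoefficientConfig,
    ScenarioSpec,
    SimulatedDataset,
    assign_treatment,
    compute_instrument,
    generate_outcome,
    simulate_dataset,
)


def _uniform_hospitals(n, pref):
    return HospitalTable(
        pd.DataFrame({"hospital_id": np.arange(1, n + 1),
                      "preference": np.full(n, pref),
                      "performance": np.zeros(n)})
    )


class TestAssignTreatment:
    def test_all_zero_coefficients_half_treated(self, zero_coefs):
        n = 50_000
        cov = generate_covariates(n, seed=0)
        hosp = _uniform_hospitals(1, 0.4)
        ids = np.ones(n, dtype=int)
        t = assign_treatment(cov, ids, hosp, zero_coefs, SCENARIOS[2], seed=1)
        assert abs(t.mean() - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_rct_treatment_independent_of_covariates(self):
        n = 20_000
        ds = simulate_dataset(
            n_patients=n, scenario=2, seed=2,
            hospital_config=HospitalConfig(n_hospitals=20, patients_per_hospital=1000),
        )
        X, names = ds.covariates.design("all")
        for j, nm in enumerate(names):
            r = np.corrcoef(ds.t, X[:, j])[0, 1]
            assert abs(r) < 0.05, nm

    def test_calibrated_hospital_treats_its_preference(self):
        """With no covariate effects, a hospital preferring 40% treats ~40%."""
        coefs = CoefficientConfig(beta_CT={}, beta_UT={})
        per = 4000
        cov = generate_covariates(3 * per, seed=3)
        hosp = _uniform_hospitals(3, 0.40)
        ids = np.repeat([1, 2, 3], per)
        t = assign_treatment(cov, ids, hosp, coefs, SCENARIOS[6], seed=4)
        for h in (1, 2, 3):
            share = t[ids == h].mean()
            assert abs(share - 0.40) < 4 * np.sqrt(0.4 * 0.6 / per)

    def test_hospital_shares_track_preferences_with_unit_slope(self):
        """Marginal calibration: treated share regresses on p_h with slope ~1."""
        ds = simulate_dataset(n_patients=15_000, scenario=6, seed=5)
        share = pd.DataFrame({"h": ds.hospital_id, "t": ds.t}).groupby("h")["t"].mean()
        pref = ds.hospitals.frame.set_index("hospital_id")["preference"]
        slope = np.polyfit(pref[share.index], share.to_numpy(), 1)[0]
        assert 0.9 < slope < 1.1

    def test_logit_offset_calibration_mode_available(self):
        cov = generate_covariates(2000, seed=6)
        hosp = _uniform_hospitals(2, 0.3)
        ids = np.repeat([1, 2], 1000)
        t = assign_treatment(cov, ids, hosp, CoefficientConfig(), SCENARIOS[6],
                             seed=7, calibration="logit_offset")
        assert set(np.unique(t)) <= {0, 1}

    def test_unknown_calibration_rejected(self):
        cov = generate_covariates(10, seed=0)
        hosp = _uniform_hospitals(1, 0.3)
        with pytest.raises(ConfigurationError, match="calibration"):
            assign_treatment(cov, np.ones(10, int), hosp, CoefficientConfig(),
                             SCENARIOS[6], seed=0, calibration="magic")


class TestGenerateOutcome:
    def test_zero_model_gives_uniform_categories(self, zero_coefs):
        import dataclasses

        coefs = dataclasses.replace(
            zero_coefs, alpha_Y=(float(logit(0.25)), 0.0, float(logit(0.75))))
        n = 100_000
        cov = generate_covariates(n, seed=8)
        hosp = _uniform_hospitals(1, 0.4)
        ids = np.ones(n, dtype=int)
        y = generate_outcome(cov, np.zeros(n), ids, hosp, coefs, SCENARIOS[1], seed=9)
        freq = np.bincount(y, minlength=5)[1:] / n
        assert np.all(np.abs(freq - 0.25) < 4 * np.sqrt(0.25 * 0.75 / n))

    def test_cumulative_odds_ratio_is_exactly_exp_beta_T(self):
        """The generator's proportional-odds property, in closed form."""
        coefs = CoefficientConfig()
        lp = 0.37  # arbitrary covariate contribution
        for k in range(3):
            a = coefs.alpha_Y[k]
            F1, F0 = expit(a + lp + coefs.beta_T), expit(a + lp)
            odds_ratio = (F1 / (1 - F1)) / (F0 / (1 - F0))
            assert odds_ratio == pytest.approx(np.exp(coefs.beta_T), rel=1e-12)
        # the benefit odds ratio for beta_T = -0.5 prints as 1.65
        assert round(float(np.exp(0.5)), 2) == 1.65

    def test_large_n_frequencies_match_closed_form(self):
        """Identical treated patients: cell frequencies hit the analytic cells."""
        m = CovariateMarginals()
        f = pd.DataFrame(
            {"age": [m.age_mean], "sex": [0], "gcs_motor": [1],
             "pupils": ["both"], "sah": [0], "ct_class": ["I"]}
        )
        n = 200_000
        cov = CovariateTable(pd.concat([f] * n, ignore_index=True), m)
        coefs = CoefficientConfig()
        hosp = _uniform_hospitals(1, 0.4)
        ids = np.ones(n, dtype=int)
        y = generate_outcome(cov, np.ones(n), ids, hosp, coefs, SCENARIOS[6], seed=10)
        F = expit(np.asarray(coefs.alpha_Y) + coefs.beta_T)
        cells = np.diff(np.concatenate([[0.0], F, [1.0]]))
        freq = np.bincount(y, minlength=5)[1:] / n
        assert np.all(np.abs(freq - cells) < 4 * np.sqrt(cells * (1 - cells) / n))

    def test_nonmonotone_cutpoints_rejected(self):
        with pytest.raises(ConfigurationError, match="increasing"):
            CoefficientConfig(alpha_Y=(0.5, 0.2, 1.0))

    def test_performance_shifts_outcomes_toward_better(self):
        """Positive eta (better hospital) raises the share of good outcomes."""
        n = 40_000
        cov = generate_covariates(n, seed=11)
        ids = np.ones(n, dtype=int)
        coefs = CoefficientConfig()
        scen = ScenarioSpec(99, "custom", performance_on=True)
        good = HospitalTable(pd.DataFrame(
            {"hospital_id": [1], "preference": [0.4], "performance": [1.0]}))
        bad = HospitalTable(pd.DataFrame(
            {"hospital_id": [1], "preference": [0.4], "performance": [-1.0]}))
        y_good = generate_outcome(cov, np.zeros(n), ids, good, coefs, scen, seed=12)
        y_bad = generate_outcome(cov, np.zeros(n), ids, bad, coefs, scen, seed=12)
        assert y_good.mean() > y_bad.mean() + 0.3


class TestInstrument:
    def test_empirical_is_within_hospital_mean(self):
        t = np.array([1, 0, 0, 1])
        ids = np.array([1, 1, 1, 1])
        np.testing.assert_allclose(compute_instrument(t, ids, "empirical"), 0.5)

    def test_leave_one_out(self):
        t = np.array([1, 0, 0, 1])
        ids = np.array([1, 1, 1, 1])
        np.testing.assert_allclose(
            compute_instrument(t, ids, "leave_one_out"), [1 / 3, 2 / 3, 2 / 3, 1 / 3]
        )

    def test_assigned_reproduces_preference(self):
        hosp = draw_hospitals(HospitalConfig(n_hospitals=3, patients_per_hospital=2), seed=0)
        ids = np.array([1, 1, 2, 2, 3, 3])
        z = compute_instrument(np.zeros(6), ids, "assigned", hospitals=hosp)
        np.testing.assert_allclose(z, hosp.preference[ids - 1])

    def test_leave_one_out_needs_two_per_hospital(self):
        with pytest.raises(DegenerateInputError):
            compute_instrument(np.array([1.0]), np.array([1]), "leave_one_out")

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_instrument(np.array([]), np.array([]))


class TestSimulatedDataset:
    def test_invariants_enforced(self, confounded_dataset):
        ds = confounded_dataset
        assert set(np.unique(ds.t)) <= {0, 1}
        assert set(np.unique(ds.y)) <= {1, 2, 3, 4}
        df = pd.DataFrame({"h": ds.hospital_id, "z": ds.z})
        assert (df.groupby("h")["z"].nunique() == 1).all()

    def test_bad_outcome_category_rejected(self, confounded_dataset):
        ds = confounded_dataset
        y = ds.y.copy()
        y[0] = 7
        with pytest.raises(ConfigurationError, match="Y"):
            SimulatedDataset(ds.covariates, ds.hospital_id, ds.hospitals, ds.z, ds.t, y)

    def test_csv_roundtrip(self, confounded_dataset, tmp_path):
        p = tmp_path / "ds.csv"
        confounded_dataset.to_csv(p)
        back = SimulatedDataset.read_csv(p)
        np.testing.assert_array_equal(back.y, confounded_dataset.y)
        np.testing.assert_array_equal(back.t, confounded_dataset.t)
        np.testing.assert_allclose(back.z, confounded_dataset.z)
        pd.testing.assert_frame_equal(
            back.covariates.frame, confounded_dataset.covariates.frame,
            check_dtype=False,
        )

    def test_scenario_gating_forces_performance_off(self):
        """Scenarios 1-6 zero the hospital performance effect."""
        ds = simulate_dataset(
            n_patients=600, scenario=6, seed=13,
            hospital_config=HospitalConfig(n_hospitals=4, patients_per_hospital=150,
                                           performance_sd=0.5),
        )
        assert np.all(ds.hospitals.performance == 0.0)

    def test_common_cause_scenario_activates_performance(self):
        ds = simulate_dataset(
            n_patients=600, scenario=7, seed=14,
            hospital_config=HospitalConfig(n_hospitals=4, patients_per_hospital=150),
        )
        assert ds.hospitals.performance.std() > 0

    def test_determinism(self):
        a = simulate_dataset(n_patients=600, scenario=6, seed=15,
                             hospital_config=HospitalConfig(n_hospitals=4, patients_per_hospital=150))
        b = simulate_dataset(n_patients=600, scenario=6, seed=15,
                             hospital_config=HospitalConfig(n_hospitals=4, patients_per_hospital=150))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
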