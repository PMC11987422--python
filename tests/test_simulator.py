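"""Simulation building blocks: randomised truth, quartiles, sampling, coverage."""

import numpy as np
import pandas as pd
import pytest

import claimsvec as cv


class TestAssignRandomTreatment:
    def test_deterministic_under_seed(self):
        a = cv.assign_random_treatment(10, seed=5)
        b = cv.assign_random_treatment(10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_law_of_large_numbers(self):
        t = cv.assign_random_treatment(100_000, p=0.5, seed=1)
        assert abs(t.mean() - 0.5) < 0.01

    def test_independent_of_outcome(self, rng):
        n = 50_000
        outcome = (rng.random(n) < 0.3).astype(int)
        t = cv.assign_random_treatment(n, seed=2)
        r = np.corrcoef(t, outcome)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


class TestPrognosticModel:
    def test_noise_covariates_give_chance_discrimination(self, rng):
        n = 2000
        features = pd.DataFrame({"z": rng.normal(size=n)})
        outcome = pd.Series((rng.random(n) < 0.3).astype(int))
        fit = cv.fit_prognostic_model(features, outcome, ["z"])
        assert fit.cstat == pytest.approx(0.5, abs=0.05)

    def test_severity_driven_outcome_strongly_discriminated(self, features50):
        fit = cv.fit_prognostic_model(
            features50,
            features50["outcome_composite"],
            ["severity", "age", "sex", "jcs_disturbed", "adl_low_admission",
             "sbp", "ckd"],
        )
        assert fit.cstat > 0.8

    def test_predictions_match_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 300
        X = rng.normal(size=(n, 2))
        y = pd.Series(
            (rng.random(n) < 1 / (1 + np.exp(-(X @ [1.0, -0.7])))).astype(int)
        )
        features = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1]})
        fit = cv.fit_prognostic_model(features, y, ["x0", "x1"])
        oracle = sm.GLM(
            y.to_numpy(), sm.add_constant(X), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.scores, oracle.fittedvalues, atol=1e-6)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            cv.fit_prognostic_model(
                pd.DataFrame({"x": [1.0, 2.0]}), pd.Series([1, 1]), ["x"]
            )


class TestQuartileBins:
    def test_scores_one_to_eight_give_two_per_bin(self):
        labels = cv.quartile_bins(np.arange(1.0, 9.0))
        assert list(labels) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_all_identical_scores_land_in_q1(self, caplog):
        with caplog.at_level("WARNING"):
            labels = cv.quartile_bins(np.full(10, 0.3))
        assert set(labels) == {1}
        assert any("identical" in r.message for r in caplog.records)

    def test_bin_sizes_nearly_equal_for_random_scores(self, rng):
        labels = cv.quartile_bins(rng.random(1003))
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 3

    def test_ties_assigned_to_lower_bin(self):
        # 25th percentile of [0,0,0,1,1,1,1,1] is 0; ties go down
        labels = cv.quartile_bins(np.array([0.0, 0.0, 0.0, 1, 1, 1, 1, 1.0]))
        assert (labels[:3] == 1).all()


class TestScenarioGrid:
    def test_endpoints_exact(self):
        grid = cv.scenario_grid(10)
        assert grid[0].weights == (0.4, 0.3, 0.2, 0.1)
        assert grid[-1].weights == (0.1, 0.2, 0.3, 0.4)

    def test_midpoint_is_uniform(self):
        grid = cv.scenario_grid(5)
        np.testing.assert_allclose(grid[2].weights, [0.25] * 4, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_weights_sum_to_one(self, n):
        for scen in cv.scenario_grid(n):
            assert sum(scen.weights) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_scenarios_rejected(self):
        with pytest.raises(ValueError):
            cv.scenario_grid(1)


@pytest.fixture(scope="module")
def pools():
    n = 8000
    ids = np.array([f"P{i}" for i in range(n)])
    treatment = (np.random.default_rng(0).random(n) < 0.5).astype(int)
    bins = np.tile([1, 2, 3, 4], n // 4)
    return ids, treatment, bins


class TestSampleSimulationCohort:

    def test_uniform_weights_split_evenly(self, pools):
        ids, treatment, bins = pools
        scen = cv.ScenarioSpec(3, (0.25, 0.25, 0.25, 0.25))
        sampled = cv.sample_simulation_cohort(
            ids, treatment, bins, scen, n_control=400, n_treated=400, seed=1
        )
        assert sampled.treated_quartile_counts == {1: 100, 2: 100, 3: 100, 4: 100}

    def test_extreme_scenario_counts(self, pools):
        ids, treatment, bins = pools
        scen = cv.ScenarioSpec(1, (0.4, 0.3, 0.2, 0.1))
        sampled = cv.sample_simulation_cohort(
            ids, treatment, bins, scen, n_control=400, n_treated=1000, seed=2
        )
        assert sampled.treated_quartile_counts == {1: 400, 2: 300, 3: 200, 4: 100}

    def test_realised_composition_matches_bookkeeping(self, pools):
        ids, treatment, bins = pools
        pos = {pid: i for i, pid in enumerate(ids)}
        scen = cv.ScenarioSpec(2, (0.4, 0.3, 0.2, 0.1))
        sampled = cv.sample_simulation_cohort(
            ids, treatment, bins, scen, n_control=800, n_treated=600, seed=3
        )
        # without replacement and quartile-exact
        assert len(set(sampled.treated_ids)) == 600
        assert len(set(sampled.control_ids)) == 800
        realised = np.bincount([bins[pos[p]] for p in sampled.treated_ids])[1:]
        assert list(realised) == [240, 180, 120, 60]
        assert all(treatment[pos[p]] == 1 for p in sampled.treated_ids)
        assert all(treatment[pos[p]] == 0 for p in sampled.control_ids)

    def test_insufficient_pool_names_quartile(self, pools):
        ids, treatment, bins = pools
        scen = cv.ScenarioSpec(1, (1.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="Q1"):
            cv.sample_simulation_cohort(
                ids, treatment, bins, scen, n_control=4, n_treated=50_000, seed=4
            )


class TestCoverage:
    def test_all_cis_cover(self):
        reps = pd.DataFrame({"ci_low": [-1.0] * 5, "ci_high": [1.0] * 5})
        assert cv.coverage(reps) == 1.0

    def test_no_ci_covers(self):
        reps = pd.DataFrame({"ci_low": [0.1, 0.2], "ci_high": [0.3, 0.4]})
        assert cv.coverage(reps) == 0.0

    def test_equals_brute_force_recount(self, rng):
        lo = rng.normal(-0.05, 0.05, 200)
        hi = lo + np.abs(rng.normal(0.1, 0.05, 200))
        reps = pd.DataFrame({"ci_low": lo, "ci_high": hi})
        brute = sum(1 for a, b in zip(lo, hi) if a <= 0 <= b) / 200
        assert cv.coverage(reps) == pytest.approx(brute)


class TestRunSimulationBookkeeping:
    def test_replicate_counts_and_determinism(self, features50, specs50):
        small = {1: specs50[1], 2: specs50[2]}
        kwargs = dict(
            scenarios=cv.scenario_grid(2)[:1],
            n_reps=2, n_control=300, n_treated=300, n_boot=50, seed=21,
            compute_cstat=False, compute_smd=False,
        )
        res = cv.run_simulation(features50, small, **kwargs)
        assert len(res.replicates) == 2 * len(small)
        assert res.n_failed == 0
        res2 = cv.run_simulation(features50, small, **kwargs)
        pd.testing.assert_frame_equal(res.replicates, res2.replicates)
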