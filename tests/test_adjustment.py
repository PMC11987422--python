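"""Propensity fitting, caliper matching, balance diagnostics, effects."""

import numpy as np
import pandas as pd
import pytest

import claimsvec as cv
from claimsvec.adjustment import MatchingError, SeparationError


def _frame(arrays, index=None):
    frame = pd.DataFrame(arrays)
    if index is not None:
        frame.index = index
    return frame


class TestFitPropensity:
    def test_constant_covariate_gives_treated_fraction(self):
        features = _frame({"x": np.ones(40)})
        t = pd.Series([1] * 12 + [0] * 28)
        fit = cv.fit_propensity(features, t, cv.ModelSpec(2, ("x",)))
        np.testing.assert_allclose(fit.ps, 12 / 40, atol=1e-8)

    def test_separation_triggers_ridge_fallback(self, caplog):
        t = pd.Series([1] * 20 + [0] * 20)
        features = _frame({"x": t.to_numpy(dtype=float)})
        with caplog.at_level("WARNING"):
            fit = cv.fit_propensity(features, t, cv.ModelSpec(2, ("x",)))
        assert fit.ridge_used
        assert any("separation" in r.message for r in caplog.records)
        assert fit.ps[t == 1].min() > 0.5 > fit.ps[t == 0].max()

    def test_separation_without_fallback_raises(self):
        t = pd.Series([1] * 20 + [0] * 20)
        features = _frame({"x": t.to_numpy(dtype=float)})
        with pytest.raises(SeparationError):
            cv.fit_propensity(
                features, t, cv.ModelSpec(2, ("x",)), ridge_on_separation=False
            )

    def test_coefficients_match_statsmodels_irls(self, rng):
        """Independent second implementation: GLM-binomial IRLS."""
        import statsmodels.api as sm

        n = 200
        X = rng.normal(size=(n, 3))
        eta = 0.3 + X @ [0.8, -0.5, 0.2]
        t = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
        features = _frame({f"x{i}": X[:, i] for i in range(3)})
        fit = cv.fit_propensity(
            features, t, cv.ModelSpec(2, ("x0", "x1", "x2")), tol=1e-12
        )
        oracle = sm.GLM(
            t.to_numpy(), sm.add_constant(X), family=sm.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.intercept, oracle.params[0], atol=1e-6)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), oracle.params[1:], atol=1e-6
        )

    def test_model1_has_no_propensity_model(self):
        with pytest.raises(ValueError):
            cv.fit_propensity(
                _frame({"x": [1.0, 2.0]}), pd.Series([0, 1]), cv.ModelSpec(1, ())
            )


class TestModelSpecs:
    def test_default_specs_satisfy_nesting(self):
        specs = cv.default_model_specs(["sev"], ["v1", "v2"])
        assert specs[1].covariates == ()
        assert specs[3].covariates == ("age", "sex", "v1", "v2")
        assert set(specs[4].covariates) == set(specs[2].covariates) | set(
            specs[3].covariates
        )


class TestMatch:
    def test_nearest_control_chosen(self):
        ps = np.array([0.5, 0.5, 0.9])
        t = np.array([1, 0, 0])
        cohort = cv.match(ps, t, ids=["T", "C1", "C2"], caliper_fraction=10.0)
        assert cohort.pairs.iloc[0]["control_id"] == "C1"
        assert cohort.n_pairs == 1

    def test_all_controls_outside_caliper_raises(self):
        ps = np.array([0.9, 0.1, 0.1])
        t = np.array([1, 0, 0])
        with pytest.raises(MatchingError):
            cv.match(ps, t, caliper_fraction=0.01)

    def test_caliper_respected_exactly(self, rng):
        ps = rng.random(400)
        t = (rng.random(400) < 0.4).astype(int)
        cohort = cv.match(ps, t, caliper_fraction=0.05, seed=3)
        gaps = (cohort.pairs["ps_treated"] - cohort.pairs["ps_control"]).abs()
        assert (gaps <= cohort.caliper + 1e-12).all()

    def test_one_to_one_without_replacement(self, rng):
        ps = rng.random(300)
        t = (rng.random(300) < 0.5).astype(int)
        cohort = cv.match(ps, t, caliper_fraction=1.0, seed=1)
        assert cohort.pairs["control_id"].is_unique
        assert cohort.pairs["treated_id"].is_unique

    def test_equals_brute_force_greedy_replay(self, rng):
        """Replay the same processing order with a naive O(n^2) greedy."""
        n = 100
        ps = rng.random(n).round(3)  # rounding forces ties
        t = (rng.random(n) < 0.4).astype(int)
        ids = np.array([f"P{i:03d}" for i in range(n)])
        cohort = cv.match(ps, t, ids=ids, caliper_fraction=0.5, seed=7)
        pos = {pid: i for i, pid in enumerate(ids)}
        available = {pid for i, pid in enumerate(ids) if t[i] == 0}
        expected = []
        for tid in cohort.treated_order:
            cands = sorted(
                available,
                key=lambda cid: (abs(ps[pos[cid]] - ps[pos[tid]]), cid),
            )
            if cands and abs(ps[pos[cands[0]]] - ps[pos[tid]]) <= cohort.caliper:
                expected.append((tid, cands[0]))
                available.remove(cands[0])
        got = list(zip(cohort.pairs["treated_id"], cohort.pairs["control_id"]))
        assert got == expected

    def test_deterministic_under_seed(self, rng):
        ps = rng.random(200)
        t = (rng.random(200) < 0.5).astype(int)
        a = cv.match(ps, t, seed=11)
        b = cv.match(ps, t, seed=11)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)


class TestSMD:
    def test_identical_groups_zero(self):
        v = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        t = pd.Series([1, 1, 1, 0, 0, 0])
        assert cv.smd(v, t) == pytest.approx(0.0)

    def test_unit_case(self):
        """Means 1 vs 0, both SD 1 -> SMD exactly 1."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std(ddof=1)
        v = pd.Series(np.r_[x + 1.0, x])
        t = pd.Series(np.r_[np.ones(500), np.zeros(500)].astype(int))
        assert cv.smd(v, t) == pytest.approx(1.0, abs=1e-12)

    def test_matches_spreadsheet_formula(self, rng):
        x_t, x_c = rng.normal(1, 2, 50), rng.normal(0, 1, 50)
        v = pd.Series(np.r_[x_t, x_c])
        t = pd.Series(np.r_[np.ones(50), np.zeros(50)].astype(int))
        manual = abs(x_t.mean() - x_c.mean()) / np.sqrt(
            (x_t.var(ddof=1) + x_c.var(ddof=1)) / 2
        )
        assert cv.smd(v, t) == pytest.approx(manual, abs=1e-12)

    def test_binary_uses_proportion_variance(self):
        v = pd.Series([1, 1, 1, 0, 1, 0, 0, 0])
        t = pd.Series([1, 1, 1, 1, 0, 0, 0, 0])
        p_t, p_c = 0.75, 0.25
        manual = (p_t - p_c) / np.sqrt((p_t * 0.25 + p_c * 0.75) / 2)
        assert cv.smd(v, t) == pytest.approx(manual, abs=1e-12)

    def test_zero_spread_flags(self):
        t = pd.Series([1, 1, 0, 0])
        assert cv.smd(pd.Series([2.0, 2.0, 2.0, 2.0]), t) == 0.0
        assert cv.smd(pd.Series([3.0, 3.0, 2.0, 2.0]), t) == np.inf


class TestMatchedCstat:
    def test_noise_covariates_give_half(self, rng):
        n = 3000
        features = _frame(
            {"z": rng.normal(size=n)}, index=[f"P{i}" for i in range(n)]
        )
        t = pd.Series((rng.random(n) < 0.5).astype(int), index=features.index)
        c = cv.matched_cstat(features, t, cv.ModelSpec(2, ("z",)))
        assert c == pytest.approx(0.5, abs=0.03)

    def test_perfect_separator_gives_one(self):
        ids = [f"P{i}" for i in range(40)]
        t = pd.Series([1] * 20 + [0] * 20, index=ids)
        features = _frame({"x": t.to_numpy(dtype=float)}, index=ids)
        assert cv.matched_cstat(features, t, cv.ModelSpec(2, ("x",))) == 1.0

    def test_auc_equals_concordant_pair_count(self, rng):
        ids = [f"P{i}" for i in range(40)]
        x = rng.normal(size=40)
        t = pd.Series((rng.random(40) < 0.5).astype(int), index=ids)
        features = _frame({"x": x}, index=ids)
        fit = cv.fit_propensity(features, t, cv.ModelSpec(2, ("x",)))
        conc = half = 0
        tv, cvals = fit.ps[t == 1], fit.ps[t == 0]
        for a in tv:
            for b in cvals:
                conc += a > b
                half += a == b
        brute = (conc + 0.5 * half) / (len(tv) * len(cvals))
        c = cv.matched_cstat(features, t, cv.ModelSpec(2, ("x",)))
        assert c == pytest.approx(brute, abs=1e-12)


class TestEstimateEffect:
    def _series(self, y, t):
        ids = [f"P{i}" for i in range(len(y))]
        return (
            pd.Series(y, index=ids, dtype=float),
            pd.Series(t, index=ids, dtype=int),
        )

    def test_fully_separated_outcome_gives_rd_one(self):
        y, t = self._series([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        est = cv.estimate_effect(y, t, n_boot=50, seed=0)
        assert est.point == pytest.approx(1.0)
        assert est.estimand == "risk_difference"

    def test_identical_outcomes_give_zero_with_ci_covering(self):
        y, t = self._series([0, 1] * 20, [1] * 20 + [0] * 20)
        est = cv.estimate_effect(y, t, n_boot=200, seed=1)
        assert est.point == pytest.approx(0.0)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_two_by_two_closed_form(self):
        # a=8 treated events of 20; c=3 control events of 30
        y, t = self._series([1] * 8 + [0] * 12 + [1] * 3 + [0] * 27,
                            [1] * 20 + [0] * 30)
        est = cv.estimate_effect(y, t, n_boot=50, seed=2)
        assert est.point == pytest.approx(8 / 20 - 3 / 30, abs=1e-12)

    def test_continuous_outcome_uses_mean_difference(self, rng):
        y, t = self._series(rng.normal(5, 2, 60), [1] * 30 + [0] * 30)
        est = cv.estimate_effect(y, t, n_boot=50, seed=3)
        assert est.estimand == "mean_difference"

    def test_nboot_lower_bound(self):
        y, t = self._series([0, 1], [0, 1])
        with pytest.raises(ValueError):
            cv.estimate_effect(y, t, n_boot=1)

    def test_matched_estimate_uses_pairs_only(self):
        ids = ["T1", "T2", "C1", "C2", "C3"]
        y = pd.Series([1.0, 0.0, 0.0, 1.0, 1.0], index=ids)
        t = pd.Series([1, 1, 0, 0, 0], index=ids)
        pairs = pd.DataFrame(
            {"treated_id": ["T1", "T2"], "control_id": ["C1", "C2"],
             "ps_treated": [0.5, 0.5], "ps_control": [0.5, 0.5]}
        )
        matched = cv.MatchedCohort(
            pairs=pairs, caliper=1.0, scale="probability",
            n_treated_unmatched=0, treated_order=["T1", "T2"],
            ps=pd.Series(0.5, index=ids),
        )
        est = cv.estimate_effect(y, t, matched=matched, n_boot=50, seed=4)
        assert est.point == pytest.approx(0.5 - 0.5)
        assert est.n == 2
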