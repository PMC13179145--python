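"""OLS, covariate screening, standardization, BH-FDR, and the battery."""

import numpy as np
import pandas as pd
import pytest

import ivdquant as iq
from ivdquant.stats import (
    BatteryConfig,
    bh_adjust,
    fit_ols,
    run_battery,
    screen_covariates,
    standardize_within,
)


def bh_oracle(p, q_star=0.05):
    """Brute-force step-up: reject H_(1..k) for the largest k with
    p_(k) <= k q*/m; q_i = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = np.minimum.accumulate(
        (m * ranked / np.arange(1, m + 1))[::-1]
    )[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    k = 0
    for i in range(m):
        if ranked[i] <= (i + 1) * q_star / m:
            k = i + 1
    reject_sorted = np.arange(m) < k
    q = np.empty(m)
    reject = np.empty(m, dtype=bool)
    q[order] = q_sorted
    reject[order] = reject_sorted
    return q, reject


class TestFitOls:
    def test_exact_linear_data(self):
        x = np.arange(10, dtype=float)
        res = fit_ols(2.0 * x, x)
        assert res.beta == pytest.approx(2.0, abs=1e-12)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)
        assert res.p < 1e-12

    def test_textbook_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 4, 5, 4, 5])
        res = fit_ols(y, x)
        assert res.beta == pytest.approx(0.6, abs=1e-12)
        # intercept from the closed form: ybar - beta*xbar = 4 - 1.8
        assert res.n == 5

    def test_matches_closed_form_with_covariates(self):
        rng = np.random.default_rng(0)
        n = 30
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 1.0 + 0.5 * x - 0.8 * z + rng.normal(0, 0.3, n)
        X = np.column_stack([np.ones(n), x, z])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        res = fit_ols(y, x, covariates=pd.DataFrame({"z": z}))
        assert res.beta == pytest.approx(beta_hat[1], abs=1e-10)
        assert res.covariates == ("z",)

    def test_ci_from_t_distribution(self):
        from scipy.stats import t as tdist
        rng = np.random.default_rng(1)
        n = 25
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(0, 1.0, n)
        res = fit_ols(y, x)
        # reconstruct the SE from the CI half-width and check the p-value
        tcrit = tdist.ppf(0.975, n - 2)
        se = (res.ci_high - res.ci_low) / (2 * tcrit)
        p = 2 * tdist.sf(abs(res.beta / se), n - 2)
        assert p == pytest.approx(res.p, rel=1e-6)

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(12, dtype=float)
        cov = pd.DataFrame({"x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(np.ones(12), x, covariates=cov)

    def test_listwise_deletion_reflected_in_n(self):
        x = np.arange(12, dtype=float)
        y = 2 * x
        y[3] = np.nan
        res = fit_ols(y, x)
        assert res.n == 11

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            fit_ols([1.0, 2.0], [1.0, 2.0])

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(2026)
        n_sim, n = 2000, 40
        rejections = 0
        for _ in range(n_sim):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if fit_ols(y, x).p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 0.015


class TestStandardize:
    def test_simple_example(self):
        assert np.allclose(standardize_within([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_affine_invariance(self):
        v = np.array([3.0, 9.0, 1.0, 4.0])
        assert np.allclose(
            standardize_within(v), standardize_within(5.0 * v - 2.0)
        )

    def test_within_stratum(self):
        v = np.array([1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        z = standardize_within(v, g)
        assert np.allclose(z[:3], z[3:])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_within([2.0, 2.0, 2.0])

    def test_standardized_beta_equals_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(0, 1, 50)
        res = fit_ols(standardize_within(y), standardize_within(x))
        assert res.beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


class TestBH:
    def test_all_small_p_rejected(self):
        rep = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert rep.reject.all()

    def test_isolated_small_p_not_rejected(self):
        rep = bh_adjust([0.04, 0.5, 0.6])
        assert not rep.reject.any()

    def test_all_ones_none_rejected(self):
        rep = bh_adjust([1.0, 1.0, 1.0])
        assert not rep.reject.any() and np.all(rep.q == 1.0)

    def test_q_at_least_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        rep = bh_adjust(p)
        assert np.all(rep.q >= p - 1e-12)

    def test_rejections_monotone_in_q_star(self):
        p = [0.001, 0.01, 0.02, 0.2, 0.6]
        r1 = bh_adjust(p, q_star=0.01).reject
        r2 = bh_adjust(p, q_star=0.05).reject
        r3 = bh_adjust(p, q_star=0.2).reject
        assert r1.sum() <= r2.sum() <= r3.sum()

    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5, 6])
    def test_matches_step_up_oracle_on_grid_vectors(self, length):
        rng = np.random.default_rng(100 + length)
        grid = np.round(np.arange(0.01, 1.001, 0.01), 2)
        for _ in range(300):
            p = rng.choice(grid, size=length)
            rep = bh_adjust(p)
            q_exp, rej_exp = bh_oracle(p)
            assert np.allclose(rep.q, q_exp, atol=1e-12)
            assert np.array_equal(rep.reject, rej_exp)

    def test_tied_p_values_against_oracle(self):
        for p in ([0.05, 0.05, 0.05], [0.01, 0.01, 0.5, 0.5],
                  [0.03, 0.03, 0.03, 0.03, 0.03, 0.03]):
            rep = bh_adjust(p)
            q_exp, rej_exp = bh_oracle(np.asarray(p))
            assert np.allclose(rep.q, q_exp)
            assert np.array_equal(rep.reject, rej_exp)


class TestScreening:
    def _table(self, n=200, age_effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame({
            "age": rng.normal(33, 6, n),
            "bmi": rng.normal(29, 5, n),
            "occ_sit_current": rng.normal(30, 30, n),
            "occ_labour_current": rng.normal(25, 40, n),
            "occ_sit_past": rng.normal(75, 100, n),
            "occ_labour_past": rng.normal(40, 60, n),
        })
        tab["t2_ms"] = 95 + age_effect * tab["age"] + rng.normal(0, 10, n)
        tab["volume_cm3"] = 10 + rng.normal(0, 1.2, n)
        return tab

    def test_planted_age_effect_selected(self):
        hits = 0
        for rep in range(50):
            tab = self._table(age_effect=-0.8, seed=rep)
            sel = screen_covariates(tab, outcomes=("t2_ms", "volume_cm3"))
            if "age" in sel:
                hits += 1
        assert hits >= 49  # power > ~99% at this effect size

    def test_pure_noise_rarely_selected(self):
        n_selected = 0
        n_tests = 0
        for rep in range(40):
            tab = self._table(age_effect=0.0, seed=1000 + rep)
            sel = screen_covariates(tab, outcomes=("t2_ms", "volume_cm3"))
            n_selected += len(sel)
            n_tests += 6
        # each candidate has ~1-(1-alpha)^2 chance of selection by chance
        rate = n_selected / n_tests
        assert rate < 0.25

    def test_per_outcome_mode(self):
        tab = self._table(age_effect=-0.8, seed=5)
        sel = screen_covariates(
            tab, outcomes=("t2_ms", "volume_cm3"), mode="per_outcome"
        )
        assert "age" in sel["t2_ms"]


@pytest.fixture(scope="module")
def planted_cohort():
    cspec = iq.CohortSpec(seed=77, beta={("t2", "L5/S1"): -0.3})
    cohort, truth = iq.generate_cohort(cspec)
    return cohort, truth


class TestBattery:

    def test_result_table_structure(self, planted_cohort):
        cohort, truth = planted_cohort
        results = run_battery(truth, cohort)
        # families: 7 levels x 5 outcomes x {simple, adjusted}
        per_level = results[results["family"].str.startswith("level:")]
        assert len(per_level) == 7 * 5 * 2
        avg = results[results["family"] == "average_spine"]
        assert len(avg) == 5 * 2
        pooled = results[results["family"].str.startswith("pooled:")]
        assert len(pooled) == 2 * 5
        assert pooled["standardized"].all()
        regions = results[results["family"].str.startswith("regions:")]
        assert len(regions) == 7 * 5 * 2
        clinical = results[results["family"] == "clinical"]
        assert len(clinical) == 4
        assert results["ci_low"].le(results["beta"]).all()
        assert results["beta"].le(results["ci_high"]).all()

    def test_planted_effect_found_at_its_level(self, planted_cohort):
        cohort, truth = planted_cohort
        results = run_battery(truth, cohort)
        row = results[
            (results["family"] == "level:L5/S1")
            & (results["outcome"] == "t2_ms") & ~results["adjusted"]
        ].iloc[0]
        assert row["ci_low"] <= -0.3 <= row["ci_high"]

    def test_q_values_present_for_fdr_families(self, planted_cohort):
        cohort, truth = planted_cohort
        results = run_battery(truth, cohort)
        fam = results[results["family"] == "level:L5/S1"]
        assert np.isfinite(fam["q"]).all()
        assert (fam["q"] >= fam["p"] - 1e-12).all()

    def test_null_cohort_rejection_rate_near_alpha(self):
        # all betas zero: per-level simple models reject at ~alpha
        n_rej, n_tests = 0, 0
        for rep in range(30):
            cspec = iq.CohortSpec(
                seed=5000 + rep, beta={}, covariate_effects={}
            )
            cohort, truth = iq.generate_cohort(cspec)
            merged = truth.merge(cohort, on="participant")
            for lv in iq.LEVELS:
                tab = merged[merged["level"] == lv]
                for outcome in ("t2_ms", "volume_cm3", "na_ratio"):
                    res = fit_ols(tab[outcome], tab["bpaq_total"])
                    n_rej += res.p < 0.05
                    n_tests += 1
        rate = n_rej / n_tests
        assert abs(rate - 0.05) < 0.03

    def test_single_participant_rejected(self):
        cspec = iq.CohortSpec(seed=1)
        cohort, truth = iq.generate_cohort(cspec)
        one = cohort.iloc[:1]
        with pytest.raises(ValueError, match="too small"):
            run_battery(truth[truth["participant"] == "P000"], one)

    def test_missing_outcome_column_fatal(self, planted_cohort):
        cohort, truth = planted_cohort
        with pytest.raises(KeyError, match="t2_ms"):
            run_battery(truth.drop(columns=["t2_ms"]), cohort)

    def test_grade_sign_inverted_in_pooled_output(self, planted_cohort):
        cohort, truth = planted_cohort
        res_inv = run_battery(truth, cohort)
        cfg = BatteryConfig(invert_grade_pooled=False)
        res_raw = run_battery(truth, cohort, cfg)
        inv = res_inv[
            (res_inv["family"] == "pooled:male")
            & (res_inv["outcome"] == "pfirrmann_inv")
        ].iloc[0]
        raw = res_raw[
            (res_raw["family"] == "pooled:male")
            & (res_raw["outcome"] == "pfirrmann")
        ].iloc[0]
        assert inv["beta"] == pytest.approx(-raw["beta"], abs=1e-10)
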