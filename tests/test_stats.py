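"""Inferential machinery: frozen hand values, calibration, robustness."""

import numpy as np
import pandas as pd
import pytest

import avmnet as av
from avmnet.stats import SweepResult, _mass_ols_tstats


class TestWelch:
    def test_cohort_age_summaries(self):
        """Unequal-variance t on the clinical cohort's printed age summaries."""
        res = av.welch_t(40.34, 13.20, 44, 45.67, 14.93, 72)
        assert res["t"] == pytest.approx(-2.01, abs=0.005)
        assert res["p"] == pytest.approx(0.048, abs=0.0005)

    def test_identical_groups(self):
        res = av.welch_t(5, 1, 10, 5, 1, 10)
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_formula(self):
        # t = -1 / sqrt(1/5 + 1/5); equal n and SD give Satterthwaite df = 8
        res = av.welch_t(1, 1, 5, 2, 1, 5)
        assert res["t"] == pytest.approx(-1 / np.sqrt(0.4), abs=1e-10)
        assert res["df"] == pytest.approx(8.0)

    def test_reduces_to_student_for_equal_variance_balanced(self):
        from scipy import stats as sps
        m1, s, n = 3.0, 1.7, 12
        m2 = 4.1
        res = av.welch_t(m1, s, n, m2, s, n)
        student = sps.ttest_ind_from_stats(m1, s, n, m2, s, n, equal_var=True)
        assert res["t"] == pytest.approx(student.statistic, abs=1e-12)
        assert res["df"] == pytest.approx(2 * n - 2)

    def test_degenerate_sds(self):
        with pytest.raises(ValueError):
            av.welch_t(1, 0, 5, 2, 0, 5)


class TestChi2:
    def test_cohort_sex_table(self):
        """Yates-corrected chi-square on the cohort's sex distribution."""
        res = av.chi2_2x2(25, 19, 29, 43)
        assert 2.37 <= res["chi2"] <= 2.38
        assert res["p"] == pytest.approx(0.123, abs=0.0005)

    def test_identical_proportions(self):
        assert av.chi2_2x2(10, 10, 10, 10)["chi2"] == 0.0
        res = av.chi2_2x2(20, 10, 40, 20)
        assert res["chi2"] == pytest.approx(0.0, abs=0.05)  # Yates keeps it near 0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            av.chi2_2x2(0, 0, 5, 5)


class TestMannWhitney:
    def test_identical_samples(self):
        res = av.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert abs(res["Z"]) < 0.2 and res["p"] > 0.9

    def test_fully_separated_exact(self):
        res = av.mann_whitney([1, 2, 3], [10, 11, 12])
        assert res["U"] in (0.0, 9.0)
        assert res["p"] == pytest.approx(0.1)  # 2/20 of all C(6,3) orderings

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        assert av.mann_whitney(x, y)["p"] < 0.01

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning):
            res = av.mann_whitney([2, 2], [2, 2, 2])
        assert res["Z"] == 0.0 and res["p"] == 1.0


class TestShapiro:
    def test_gaussian_calibration(self):
        rng = np.random.default_rng(1)
        ps = [av.shapiro_wilk(rng.normal(size=100))["p"] for _ in range(50)]
        assert np.mean(np.array(ps) > 0.05) >= 0.9

    def test_exponential_power(self):
        rng = np.random.default_rng(2)
        ps = [av.shapiro_wilk(rng.exponential(size=100))["p"] for _ in range(50)]
        assert np.mean(np.array(ps) < 0.05) >= 0.9

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            av.shapiro_wilk([1.0, 1.0, 1.0, 1.0])

    def test_size_bounds(self):
        with pytest.raises(ValueError):
            av.shapiro_wilk([1.0, 2.0])


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = av.ols_fit(2 * x + 1, x[:, None], terms=["x"])
        assert res.beta == pytest.approx([1.0, 2.0], abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_standardized_betas_match_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        res = av.ols_fit(y, x[:, None], terms=["x"], standardized=True)
        assert res["x"]["beta"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            av.ols_fit(rng.normal(size=30), X)


class TestHuberRLM:
    def test_exact_line(self):
        x = np.arange(12.0)
        res = av.huber_rlm_fit(2 * x + 1, x[:, None], terms=["x"])
        assert res.beta == pytest.approx([1.0, 2.0], abs=1e-6)

    def test_clean_data_close_to_ols(self, rng):
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(size=100)
        ols = av.ols_fit(y, x[:, None], terms=["x"])
        rlm = av.huber_rlm_fit(y, x[:, None], terms=["x"])
        assert abs(rlm["x"]["beta"] - ols["x"]["beta"]) < 2 * ols["x"]["se"]

    def test_large_c_converges_to_ols(self, rng):
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(size=60)
        y[0] += 10
        ols = av.ols_fit(y, x[:, None], terms=["x"])
        rlm = av.huber_rlm_fit(y, x[:, None], terms=["x"], c=1e6)
        np.testing.assert_allclose(rlm.beta, ols.beta, atol=1e-6)

    def test_downweights_gross_outlier(self, rng):
        x = rng.uniform(-2, 2, 50)
        y = 2 * x + rng.normal(0, 0.5, 50)
        y[7] += 50.0
        ols = av.ols_fit(y, x[:, None], terms=["x"])
        rlm = av.huber_rlm_fit(y, x[:, None], terms=["x"])
        assert abs(rlm["x"]["beta"] - 2) < abs(ols["x"]["beta"] - 2)


class TestBhFdr:
    def test_hand_step_up(self):
        out = av.bh_fdr([0.01, 0.02, 0.04])
        np.testing.assert_allclose(out["adjusted"], [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_and_equal(self):
        np.testing.assert_allclose(av.bh_fdr([0.03])["adjusted"], [0.03])
        np.testing.assert_allclose(av.bh_fdr([0.2, 0.2, 0.2])["adjusted"], [0.2] * 3)

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.uniform(size=40)
        adj = av.bh_fdr(p)["adjusted"]
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            av.bh_fdr([0.1, 1.5])


class TestEdgewise:
    @staticmethod
    def _stack(rng, n_sub, n=12, shift=None):
        mats = []
        for _ in range(n_sub):
            w = np.triu(rng.normal(0.2, 0.2, (n, n)), 1)
            if shift is not None:
                w[shift[0], shift[1]] += shift[2]
            w = np.clip(w + w.T, -0.95, 0.95)
            np.fill_diagonal(w, 0.0)
            mats.append(av.ConnectivityMatrix(weights=w, modality="FC"))
        return mats

    def test_null_groups_give_small_mean_t(self, rng):
        a = self._stack(rng, 30)
        b = self._stack(rng, 30)
        out = av.edgewise_group_ttest(a, b, k=10)
        iu = np.triu_indices(12, k=1)
        assert abs(np.nanmean(out["tmat"][iu])) < 0.1

    def test_planted_edge_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = self._stack(rng, 25, shift=(2, 5, 0.3))
            b = self._stack(rng, 25)
            out = av.edgewise_group_ttest(a, b, k=10)
            if (3, 6) in out["hyper_edges"]:
                hits += 1
        assert hits >= 19

    def test_k_larger_than_edges_warns(self, rng):
        a = self._stack(rng, 5, n=5)
        b = self._stack(rng, 5, n=5)
        with pytest.warns(UserWarning):
            out = av.edgewise_group_ttest(a, b, k=1000)
        assert len(out["hyper_edges"]) + len(out["hypo_edges"]) <= 2 * 10

    def test_covariate_adjustment_runs(self, rng):
        a = self._stack(rng, 10)
        b = self._stack(rng, 10)
        cov = pd.DataFrame({"mFD": rng.uniform(0.05, 0.3, 20)})
        out = av.edgewise_group_ttest(a, b, covariates=cov, k=5)
        assert np.isfinite(out["tmat"][np.triu_indices(12, 1)]).all()


class TestAggregateStrength:
    def test_single_edge(self, template_sc40):
        assert av.aggregate_edge_strength(template_sc40, [(1, 2)]) == \
            template_sc40.weights[0, 1]

    def test_uniform_edges(self):
        w = np.ones((4, 4)) - np.eye(4)
        mat = av.ConnectivityMatrix(weights=0.6 * w, modality="FC")
        assert av.aggregate_edge_strength(mat, [(1, 2), (2, 3), (1, 4)]) == \
            pytest.approx(0.6)

    def test_empty_set_rejected(self, template_sc40):
        with pytest.raises(ValueError):
            av.aggregate_edge_strength(template_sc40, [])


class TestMorphometryTmap:
    @staticmethod
    def _values(rng, n_sub=30, n_parcels=15, effect=None):
        base = rng.normal(2.5, 0.1, (n_sub, n_parcels))
        if effect is not None:
            parcel, size, groups = effect
            base[groups == "AVM", parcel] += size
        return pd.DataFrame(base, columns=[f"P{i}" for i in range(n_parcels)])

    def test_identical_groups_near_zero(self, rng):
        groups = np.array(["AVM"] * 15 + ["NC"] * 15)
        vals = self._values(rng)
        tmap = av.regional_morphometry_tmap(vals, groups)
        assert np.nanmean(np.abs(tmap.tstat)) < 1.0

    def test_planted_parcel_is_extreme(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = np.array(["AVM"] * 15 + ["NC"] * 15)
            vals = self._values(rng, effect=(4, 0.3, groups))
            tmap = av.regional_morphometry_tmap(vals, groups)
            if np.nanargmax(np.abs(tmap.tstat)) == 4:
                hits += 1
        assert hits >= 19

    def test_tiv_confound_removed(self, rng):
        n = 40
        groups = np.array(["AVM"] * 20 + ["NC"] * 20)
        tiv = np.where(groups == "AVM", 1.6e6, 1.4e6) + rng.normal(0, 3e4, n)
        vals = pd.DataFrame(
            rng.normal(2.5, 0.05, (n, 10)) + 1e-6 * (tiv[:, None] - 1.5e6))
        cov = pd.DataFrame({"TIV": tiv})
        adj = av.regional_morphometry_tmap(vals, groups, covariates=cov)
        raw = av.regional_morphometry_tmap(vals, groups)
        assert np.nanmean(np.abs(adj.tstat)) < np.nanmean(np.abs(raw.tstat))
        assert np.nanmax(np.abs(adj.tstat)) < 3.0

    def test_constant_parcel_flagged(self, rng):
        groups = np.array(["AVM"] * 5 + ["NC"] * 5)
        vals = self._values(rng, n_sub=10)
        vals.iloc[:, 3] = 2.5
        tmap = av.regional_morphometry_tmap(vals, groups)
        assert np.isnan(tmap.tstat[3])


class TestSensitivitySweep:
    def test_strong_effect_robust(self):
        sweep = av.sensitivity_sweep(lambda d, c: {"beta": 2.0 + d, "p": 0.001})
        assert isinstance(sweep, SweepResult) and sweep.robust

    def test_noise_not_robust(self):
        rng = np.random.default_rng(0)

        def fit(d, c):
            return {"beta": rng.normal(), "p": float(rng.uniform())}

        assert not av.sensitivity_sweep(fit).robust

    def test_single_point_degenerate(self):
        sweep = av.sensitivity_sweep(lambda d, c: {"beta": 1.0, "p": 0.01},
                                     density_grid=[0.1], lesion_cutoff_grid=[0.5])
        assert sweep.robust and sweep.degenerate_grid

    def test_failed_cell_recorded_and_breaks_robustness(self):
        def fit(d, c):
            if d > 0.15:
                raise RuntimeError("boom")
            return {"beta": 1.0, "p": 0.01}

        sweep = av.sensitivity_sweep(fit)
        assert sweep.table["failed"].any() and not sweep.robust


def test_mass_ols_matches_statsmodels(rng):
    """Vectorized per-column t-statistics agree with a full statsmodels fit."""
    import statsmodels.api as sm
    X = np.column_stack([np.ones(40), rng.normal(size=40), rng.uniform(size=40)])
    Y = rng.normal(size=(40, 6))
    t, p = _mass_ols_tstats(Y, X, term_idx=1)
    for j in range(6):
        fit = sm.OLS(Y[:, j], X).fit()
        assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert p[j] == pytest.approx(fit.pvalues[1], abs=1e-10)
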