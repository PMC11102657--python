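"""Covariate-adjusted tests, FDR, effect sizes, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from wmtopo import (
    InferenceConfig,
    adjusted_group_test,
    bh_fdr,
    cohens_d_from_t,
    partial_correlation,
    residualize,
    run_group_analysis,
)


class TestResidualize:
    def test_orthogonal_covariates_reduce_to_centering(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        x = np.zeros((40, 1))  # constant covariate: absorbed by intercept
        with pytest.raises(ValueError):
            residualize(y, x)  # rank-deficient with the intercept
        np.testing.assert_allclose(residualize(y, None), y - y.mean())

    def test_exact_linear_dependence_gives_zero_residuals(self):
        x = np.linspace(0, 1, 30)
        y = 2.0 + 3.0 * x
        assert np.allclose(residualize(y, x[:, None]), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        r = residualize(y, X)
        for j in range(3):
            assert abs(r @ X[:, j]) < 1e-8 * np.linalg.norm(X[:, j])


class TestAdjustedGroupTest:
    def _null_data(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        groups = np.array(["patient"] * n + ["control"] * n)
        return rng.normal(size=2 * n), groups

    def test_reduces_to_pooled_t_without_covariates(self):
        values, groups = self._null_data(3)
        res = adjusted_group_test(values, groups, covariates=None)
        t_ref, p_ref = sps.ttest_ind(
            values[groups == "patient"], values[groups == "control"], equal_var=True
        )
        assert res.t == pytest.approx(float(t_ref))
        assert res.p == pytest.approx(float(p_ref))
        assert res.df == 58

    def test_constant_covariates_reduce_to_pooled_t(self):
        values, groups = self._null_data(4)
        cov = np.ones((60, 2))  # constant columns are dropped
        for mode in ("ancova", "residualize"):
            res = adjusted_group_test(values, groups, cov, mode=mode)
            t_ref, _ = sps.ttest_ind(
                values[groups == "patient"], values[groups == "control"],
                equal_var=True,
            )
            assert res.t == pytest.approx(float(t_ref))

    def test_modes_agree_on_orthogonalized_designs(self):
        # both modes test the same hypothesis; on balanced data with
        # group-orthogonal covariates they give nearly identical t
        rng = np.random.default_rng(9)
        values, groups = self._null_data(9)
        cov = rng.normal(size=(60, 2))
        cov -= cov.mean(axis=0)
        t_a = adjusted_group_test(values, groups, cov, mode="ancova").t
        t_r = adjusted_group_test(values, groups, cov, mode="residualize").t
        assert t_a == pytest.approx(t_r, abs=0.15)

    def test_permutation_calibration(self):
        # the parametric p matches the permutation frequency of larger |t|
        rng = np.random.default_rng(12)
        values, groups = self._null_data(12)
        cov = rng.normal(size=(60, 2))
        obs = adjusted_group_test(values, groups, cov)
        n_perm, exceed = 1000, 0
        for _ in range(n_perm):
            perm = rng.permutation(len(groups))
            res = adjusted_group_test(values, groups[perm], cov)
            exceed += abs(res.t) >= abs(obs.t)
        assert exceed / n_perm == pytest.approx(obs.p, abs=0.05)

    def test_constant_values_signaled(self):
        _, groups = self._null_data()
        with pytest.raises(ValueError, match="constant"):
            adjusted_group_test(np.ones(60), groups)

    def test_sign_convention_patient_minus_control(self):
        values, groups = self._null_data(5)
        values[groups == "patient"] -= 5.0
        res = adjusted_group_test(values, groups)
        assert res.t < 0


class TestCohensD:
    def test_zero_t_gives_zero_d(self):
        assert cohens_d_from_t(0.0, 30, 30) == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 1, 30)

    def test_closed_form(self):
        assert cohens_d_from_t(-3.75, 30, 30) == pytest.approx(
            3.75 * np.sqrt(2 / 30)
        )


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.04, 0.03]), [0.015, 0.04, 0.04]
        )

    def test_equal_ps_stay_equal(self):
        out = bh_fdr([0.02, 0.02, 0.02, 0.02])
        np.testing.assert_allclose(out, 0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_order_invariance_and_dominance(self, ps):
        ps = np.asarray(ps)
        out = bh_fdr(ps)
        assert np.all(out >= ps - 1e-12)
        assert np.all(out <= 1.0)
        perm = np.random.default_rng(0).permutation(len(ps))
        np.testing.assert_allclose(bh_fdr(ps[perm]), out[perm])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(float(r_ref))
        assert res.p == pytest.approx(float(p_ref), rel=1e-6)

    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 20)
        res = partial_correlation(x, x.copy() * 2 + 1)
        assert res.r == pytest.approx(1.0)

    def test_reported_r_implies_reported_p(self):
        # r = -0.6466, n = 30, 3 covariates: df = 25, t ~ -4.24, p ~ 3e-4
        r, df = -0.6466, 25
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
        assert t == pytest.approx(-4.236, abs=0.01)
        assert p == pytest.approx(2.7e-4, rel=0.05)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.normal(size=(35, 4)), columns=["x", "y", "c1", "c2"]
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        res = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_symmetry_and_covariate_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        a = partial_correlation(x, y, cov)
        b = partial_correlation(y, x, cov)
        assert a.r == pytest.approx(b.r)
        c = partial_correlation(x, y, cov * 3.5 - 7.0)
        assert a.r == pytest.approx(c.r)

    def test_zero_residual_variance_signaled(self):
        cov = np.linspace(0, 1, 20)[:, None]
        with pytest.raises(ValueError, match="residual"):
            partial_correlation(2 * cov[:, 0] + 1, np.random.default_rng(0).normal(size=20), cov)


class TestRunGroupAnalysis:
    def _toy_tables(self, seed=0, n=12, n_nodes=5, missing=False):
        rng = np.random.default_rng(seed)
        ids = [f"S{i}" for i in range(2 * n)]
        global_aucs = pd.DataFrame(
            rng.normal(size=(2 * n, 7)),
            index=ids,
            columns=["aCp", "aLp", "aEg", "aEloc", "aGamma", "aLambda", "aSigma"],
        )
        nodal = {
            "efficiency": pd.DataFrame(
                rng.normal(size=(2 * n, n_nodes)), index=ids,
                columns=[f"N{i}" for i in range(n_nodes)],
            )
        }
        meta = pd.DataFrame(
            {
                "group": ["patient"] * n + ["control"] * n,
                "age": rng.normal(63, 6, 2 * n),
                "sex": rng.choice(["M", "F"], 2 * n),
                "education": rng.normal(11, 3, 2 * n),
                "FBI_apathy": rng.normal(10, 3, 2 * n),
                "FBI_disinhibition": rng.normal(8, 3, 2 * n),
            },
            index=ids,
        )
        if missing:
            meta.loc["S0", "FBI_apathy"] = np.nan
        return global_aucs, nodal, meta

    def test_family_bookkeeping(self):
        g, nod, meta = self._toy_tables()
        res = run_group_analysis(g, nod, meta)
        assert len(res.global_tests) == 7
        assert len(res.nodal_tests["efficiency"]) == 5
        # FDR within the global family of 7
        ps = [s.p for s in res.global_tests]
        np.testing.assert_allclose(
            [s.p_fdr for s in res.global_tests], bh_fdr(ps)
        )
        # 5 nodes x 2 scores correlation family
        assert len(res.correlations) == 10

    def test_missing_score_drops_subject(self):
        g, nod, meta = self._toy_tables(missing=True)
        res = run_group_analysis(g, nod, meta)
        assert res.dropped.get("FBI_apathy") == 1
        n_by_score = {c.score: c.n for c in res.correlations}
        assert n_by_score["FBI_apathy"] == n_by_score["FBI_disinhibition"] - 1
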