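"""SWC, correlation semimatrix, hierarchical partitioning, PCA, regressions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import commstruct as cs
from commstruct.community import EnvTable


def _env_from_array(X, names):
    return EnvTable(pd.DataFrame(
        X, columns=names, index=[f"p{i}" for i in range(X.shape[0])]))


class TestSwc:
    def test_formula(self):
        assert cs.soil_water_content(12.0, 10.0) == pytest.approx(0.2)

    def test_dry_soil(self):
        assert cs.soil_water_content(10.0, 10.0) == 0.0

    @pytest.mark.parametrize("fresh,dry", [(5.0, 0.0), (5.0, -1.0), (4.0, 5.0)])
    def test_invalid_masses(self, fresh, dry):
        with pytest.raises(ValueError):
            cs.soil_water_content(fresh, dry)


class TestSemimatrix:
    def test_copy_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        env = _env_from_array(np.column_stack([x, x, -x]), ["a", "b", "c"])
        out = cs.pearson_semimatrix(env, ["a", "b", "c"])
        r = {(row.factor1, row.factor2): row.r for row in out.itertuples()}
        assert r[("b", "a")] == pytest.approx(1.0)
        assert r[("c", "a")] == pytest.approx(-1.0)

    def test_lower_triangle_shape(self):
        rng = np.random.default_rng(1)
        env = _env_from_array(rng.normal(size=(10, 4)), list("abcd"))
        out = cs.pearson_semimatrix(env, list("abcd"))
        assert len(out) == 6

    def test_zero_variance_flagged(self):
        env = _env_from_array(
            np.column_stack([np.ones(10), np.arange(10.0)]), ["a", "b"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cs.pearson_semimatrix(env, ["a", "b"])
        assert np.isnan(out["r"]).all()


class TestHierarchicalPartition:
    def _make(self, n, k, seed, corr=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        if corr:
            for j in range(1, k):
                X[:, j] = corr * X[:, 0] + np.sqrt(1 - corr**2) * X[:, j]
        names = [f"f{j}" for j in range(k)]
        return X, names, rng

    def test_single_predictor_gets_everything(self):
        X, names, rng = self._make(30, 1, 0)
        y = pd.Series(0.7 * X[:, 0] + rng.normal(size=30),
                      index=[f"p{i}" for i in range(30)])
        env = _env_from_array(X, names)
        res = cs.hierarchical_partition(y, env, names)
        assert res.independent[0] == pytest.approx(res.r2_full, abs=1e-12)
        assert res.independent_pct[0] == pytest.approx(100.0)

    def test_orthogonal_predictors_independent_equals_marginal(self):
        """With exactly orthogonal predictors, I_i = marginal R^2_i
        (verified against explicit enumeration of the 4 subsets)."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        b -= a * (a @ b) / (a @ a)  # exact orthogonalization
        y_vals = 1.0 * a + 0.5 * b + rng.normal(size=40) * 0.3
        env = _env_from_array(np.column_stack([a, b]), ["a", "b"])
        y = pd.Series(y_vals, index=env.plots)
        res = cs.hierarchical_partition(y, env, ["a", "b"])

        def r2(X):
            A = np.column_stack([np.ones(40)] + X)
            coef, *_ = np.linalg.lstsq(A, y_vals, rcond=None)
            resid = y_vals - A @ coef
            yc = y_vals - y_vals.mean()
            return 1 - resid @ resid / (yc @ yc)

        # y is not centered against the predictors, so orthogonality of the
        # centered columns is what matters; allow small numerical slack
        assert res.independent[0] == pytest.approx(r2([a]), abs=1e-2)
        assert res.independent[1] == pytest.approx(r2([b]), abs=1e-2)
        assert res.joint.sum() == pytest.approx(0.0, abs=1e-2)

    def test_shapley_identity_random_designs(self):
        """sum of independent contributions = full-model R^2 to 1e-9,
        including correlated designs."""
        for seed, corr in [(0, 0.0), (1, 0.5), (2, 0.8)]:
            X, names, rng = self._make(35, 3, seed, corr)
            y = pd.Series(X @ [1.0, -0.5, 0.25] + rng.normal(size=35),
                          index=[f"p{i}" for i in range(35)])
            env = _env_from_array(X, names)
            res = cs.hierarchical_partition(y, env, names)
            assert res.independent.sum() == pytest.approx(res.r2_full, abs=1e-9)
            assert (res.independent <= res.r2_full + 1e-9).all()
            assert res.independent_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_order_invariance(self):
        X, names, rng = self._make(30, 4, 7, 0.4)
        y = pd.Series(X @ [1, 0.5, 0.2, -0.3] + rng.normal(size=30),
                      index=[f"p{i}" for i in range(30)])
        env = _env_from_array(X, names)
        base = cs.hierarchical_partition(y, env, names)
        perm = ["f2", "f0", "f3", "f1"]
        out = cs.hierarchical_partition(y, env, perm)
        for name, val in zip(perm, out.independent):
            assert val == pytest.approx(
                base.independent[names.index(name)], abs=1e-12
            )

    def test_collinear_pair_refused(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        env = _env_from_array(np.column_stack([x, 2 * x + 1e-9]), ["a", "mat"])
        y = pd.Series(x + rng.normal(size=30) * 0.1, index=env.plots)
        with pytest.raises(ValueError, match="collinear"):
            cs.hierarchical_partition(y, env, ["a", "mat"])

    def test_too_many_predictors(self):
        X, names, rng = self._make(40, 13, 0)
        env = _env_from_array(X, names)
        y = pd.Series(rng.normal(size=40), index=env.plots)
        with pytest.raises(ValueError, match="12"):
            cs.hierarchical_partition(y, env, names)


class TestPca:
    def test_two_correlated_factors_one_axis(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        env = _env_from_array(np.column_stack([x, 2 * x]), ["a", "b"])
        res = cs.pca_env(env, ["a", "b"], 2)
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_properties_random_table(self):
        rng = np.random.default_rng(5)
        env = _env_from_array(rng.normal(size=(60, 8)), list("abcdefgh"))
        res = cs.pca_env(env, list("abcdefgh"), 8)
        assert np.all(np.diff(res.pct_variance) <= 1e-12)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(8), atol=1e-10
        )
        # scores have zero mean and diagonal covariance = eigenvalues
        S = res.scores.values
        np.testing.assert_allclose(S.mean(axis=0), 0, atol=1e-9)
        cov = np.cov(S, rowvar=False)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-9)

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        env = _env_from_array(rng.normal(size=(30, 3)), list("abc"))
        res = cs.pca_env(env, list("abc"), 2)
        for a in range(2):
            top = np.argmax(np.abs(res.loadings[:, a]))
            assert res.loadings[top, a] > 0

    def test_constant_factor_named(self):
        env = _env_from_array(
            np.column_stack([np.ones(10), np.arange(10.0)]), ["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            cs.pca_env(env, ["flat", "x"], 1)


class TestGradientRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        env = _env_from_array(x[:, None], ["elevation"])
        y = pd.Series(2 * x + 1, index=env.plots)
        out = cs.gradient_regression(y, env, "elevation")
        assert out["slope"] == pytest.approx(2.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_response_convention(self):
        env = _env_from_array(np.arange(5.0)[:, None], ["elevation"])
        y = pd.Series(3.0, index=env.plots)
        out = cs.gradient_regression(y, env, "elevation")
        assert out["slope"] == 0.0 and out["p"] == 1.0

    def test_quadratic_power_u_shape(self):
        """A U-shaped response: quadratic term significant in >= 90% of 100
        replicates at noise sd 0.5 over a unit-curvature parabola."""
        rng = np.random.default_rng(11)
        x = np.linspace(-3, 3, 30)
        env = _env_from_array(x[:, None], ["elevation"])
        hits = 0
        for rep in range(100):
            y = pd.Series((x - x.mean()) ** 2 + rng.normal(size=30) * 0.5,
                          index=env.plots)
            out = cs.gradient_regression(y, env, "elevation", quadratic=True)
            hits += out["p_quadratic"] <= 0.05
        assert hits >= 90
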