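"""RDA, permutation tests, selection, GAM, SEM, Durbin-Watson, loess."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedapipe.drivers import (
    durbin_watson,
    forward_select,
    gam_poisson,
    loess_smooth,
    piecewise_sem,
    pillai_test,
    rda,
    transform_fourth_root,
)


def brute_rda_eigenvalues(Y, X):
    """Independent oracle: explicit projection matrix + eigen-decomposition."""
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    P = Xs @ np.linalg.inv(Xs.T @ Xs) @ Xs.T
    F = P @ Yc
    lam = np.linalg.eigvalsh(F.T @ F)[::-1] / (n - 1)
    return lam[lam > 1e-12]


class TestTransform:
    def test_fourth_root_values(self):
        np.testing.assert_allclose(
            transform_fourth_root(np.array([0.0, 1.0, 16.0])), [0.0, 1.0, 2.0]
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            transform_fourth_root(np.array([-1.0]))


class TestRDA:
    def test_exact_linear_response_explains_everything(self, rng):
        X = rng.normal(size=(30, 2))
        B = rng.normal(size=(2, 5))
        Y = X @ B
        r = rda(Y, X)
        assert r.proportion_explained == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_covariate_explains_nothing(self):
        n = 40
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        Y = np.column_stack([np.sin(t), np.sin(2 * t)])
        X = np.column_stack([np.cos(t)])  # orthogonal to both responses
        r = rda(Y, X)
        assert r.proportion_explained == pytest.approx(0.0, abs=1e-8)

    def test_eigenvalues_match_projection_oracle(self, rng):
        for _ in range(10):
            n, m, p = 25, int(rng.integers(2, 7)), int(rng.integers(1, 4))
            Y = rng.normal(size=(n, m))
            X = rng.normal(size=(n, p))
            r = rda(Y, X)
            expect = brute_rda_eigenvalues(Y, X)
            np.testing.assert_allclose(r.eigenvalues, expect, atol=1e-10)

    def test_variance_decomposition(self, rng):
        Y = rng.normal(size=(30, 4))
        X = rng.normal(size=(30, 3))
        r = rda(Y, X)
        Yc = Y - Y.mean(axis=0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
        resid = Yc - Xs @ B
        unconstrained = (resid**2).sum() / 29
        assert r.constrained_inertia + unconstrained == pytest.approx(
            r.total_inertia, abs=1e-10
        )

    def test_collinear_covariates_named(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        Y = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="a|b"):
            rda(Y, X)


class TestPillai:
    def test_perfect_relationship_gives_minimal_p(self, rng):
        X = rng.normal(size=(20, 2))
        Y = X.copy()
        out = pillai_test(Y, X, n_perm=99, seed=0)
        assert out["p_value"] == pytest.approx(1 / 100)

    def test_seed_reproducibility(self, rng):
        Y = rng.normal(size=(20, 3))
        X = rng.normal(size=(20, 2))
        a = pillai_test(Y, X, n_perm=99, seed=5)
        b = pillai_test(Y, X, n_perm=99, seed=5)
        assert a["p_value"] == b["p_value"]

    def test_partial_term_detects_only_active_variable(self, rng):
        n = 40
        X = pd.DataFrame({"active": rng.normal(size=n), "noise": rng.normal(size=n)})
        Y = np.outer(X["active"], [1.0, -0.5, 0.8]) + 0.2 * rng.normal(size=(n, 3))
        p_active = pillai_test(Y, X, term="active", n_perm=199, seed=1)["p_value"]
        p_noise = pillai_test(Y, X, term="noise", n_perm=199, seed=2)["p_value"]
        assert p_active == pytest.approx(1 / 200)  # beyond every permutation
        assert p_noise > p_active  # noise term p is just uniform, not extreme


class TestForwardSelect:
    def test_recovers_single_active_covariate(self, rng):
        n = 60
        X = pd.DataFrame(
            {"driver": rng.normal(size=n),
             **{f"n{k}": rng.normal(size=n) for k in range(5)}}
        )
        Y = np.outer(X["driver"], rng.normal(size=4)) + 0.5 * rng.normal(size=(n, 4))
        out = forward_select(Y, X, n_perm=199, seed=3)
        assert "driver" in out["selected"]
        assert len(out["selected"]) <= 2

    def test_duplicated_column_never_co_selected(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=n)})
        Y = np.outer(x, [1.0, 1.0]) + 0.3 * rng.normal(size=(n, 2))
        out = forward_select(Y, X, n_perm=99, seed=4)
        assert not {"a", "a_copy"} <= set(out["selected"])


class TestDurbinWatson:
    def test_white_noise_near_two(self):
        e = np.random.default_rng(0).normal(size=1000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.15)

    def test_alternating_residuals_in_upper_regime(self):
        e = np.resize([1.0, -1.0], 100)
        assert durbin_watson(e) > 3.5

    def test_zero_residuals_error(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(10))


class TestGAM:
    def test_infinite_penalty_matches_poisson_glm(self, rng):
        n = 80
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(1.0 + 1.5 * x))
        X = pd.DataFrame({"x": x})
        res = gam_poisson(y, X, alphas={"x": 1e12}, screen_outliers=False)
        # reference: plain Poisson GLM with a linear term (IRLS via statsmodels)
        import statsmodels.api as sm

        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(
            res.linear_predictor, glm.predict(sm.add_constant(x), which="linear"),
            atol=1e-6,
        )

    def test_hump_shaped_effect_recovered(self):
        rng = np.random.default_rng(42)
        n = 60
        x = rng.uniform(-2, 2, n)
        true_max = 0.4
        eta = 2.5 - 0.8 * (x - true_max) ** 2  # quadratic on the log scale
        y = rng.poisson(np.exp(eta))
        res = gam_poisson(y, pd.DataFrame({"x": x}), screen_outliers=False)
        grid = res.prediction_grid["x"]
        xmax = grid.x[grid["mean"].idxmax()]
        assert abs(xmax - true_max) < 0.1 * np.ptp(x)
        # interior, hence genuinely non-monotone
        assert grid.x.min() < xmax < grid.x.max()

    def test_null_covariate_shrinks_flat(self):
        rng = np.random.default_rng(7)
        n = 80
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(2.0 + 0 * x))
        res = gam_poisson(y, pd.DataFrame({"x": x}), screen_outliers=False)
        assert res.edf_per_smooth["x"] < 2.5
        band = res.prediction_grid["x"]
        flat = np.exp(2.0)
        assert ((band.lower < flat) & (flat < band.upper)).mean() > 0.9

    def test_outlier_screening_flags_and_removes(self):
        rng = np.random.default_rng(9)
        n = 50
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(2.0 + 0.5 * x))
        y[13] = 300  # gross outlier
        res = gam_poisson(y, pd.DataFrame({"x": x}), ages=np.arange(n, dtype=float))
        assert 13 in res.outliers
        assert 13 not in res.used_index
        assert 0 <= res.dw_statistic <= 4

    def test_non_integer_richness_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            gam_poisson(np.array([1.5, 2.0]), pd.DataFrame({"x": [0.0, 1.0]}))


class TestSEM:
    @staticmethod
    def gen_chain(rng, n=300, beta=0.5):
        """x -> m -> y with known standardized effects."""
        x = rng.normal(size=n)
        m = beta * x + rng.normal(size=n) * np.sqrt(1 - beta**2)
        y = beta * m + rng.normal(size=n) * np.sqrt(1 - beta**2)
        return pd.DataFrame({"x": x, "m": m, "y": y})

    def test_standardized_coefficients_recovered(self, rng):
        data = self.gen_chain(rng, n=2000, beta=0.6)
        res = piecewise_sem([("x", "m"), ("m", "y")], data)
        coefs = res.paths.set_index(["from", "to"])["std_coefficient"]
        assert coefs[("x", "m")] == pytest.approx(0.6, abs=0.06)
        assert coefs[("m", "y")] == pytest.approx(0.6, abs=0.06)
        assert res.df == 2  # one claim: x indep y given m
        assert res.p_value > 0.01

    def test_saturated_dag_has_no_claims(self, rng):
        data = self.gen_chain(rng)
        res = piecewise_sem([("x", "m"), ("m", "y"), ("x", "y")], data)
        assert res.fisher_c == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_omitted_edge_detected(self, rng):
        # truth: x -> m -> y plus a direct x -> y path; fitting the pure
        # chain leaves the claim x _||_ y | m, which the data violate
        n = 400
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(size=n)
        y = 0.5 * m + 0.5 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        res = piecewise_sem([("x", "m"), ("m", "y")], data)
        assert res.p_value < 0.05

    def test_cyclic_dag_rejected(self, rng):
        data = self.gen_chain(rng)
        with pytest.raises(ValueError, match="acyclic"):
            piecewise_sem([("x", "m"), ("m", "x")], data)

    def test_missing_variable_rejected(self, rng):
        data = self.gen_chain(rng)
        with pytest.raises(ValueError, match="ghost"):
            piecewise_sem([("x", "ghost")], data)

    def test_marginal_r2_reported(self, rng):
        data = self.gen_chain(rng, n=1000, beta=0.7)
        res = piecewise_sem([("x", "m"), ("m", "y")], data)
        assert res.marginal_r2["m"] == pytest.approx(0.49, abs=0.08)


class TestLoess:
    def test_constant_series_unchanged(self):
        y = np.full(30, 3.0)
        np.testing.assert_allclose(loess_smooth(y, span=0.3), y, atol=1e-10)

    def test_exact_line_reproduced_with_full_span(self):
        x = np.arange(40, dtype=float)
        y = 2.0 + 0.5 * x
        np.testing.assert_allclose(loess_smooth(y, x=x, span=1.0), y, atol=1e-8)

    def test_matches_independent_local_fit(self, rng):
        n = 60
        x = np.sort(rng.uniform(0, 10, n))
        y = np.sin(x) + 0.1 * rng.normal(size=n)
        got = loess_smooth(y, x=x, span=0.4, degree=2)
        q = int(np.ceil(0.4 * n))
        expect = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:q]
            h = d[idx].max()
            w = (1 - (d[idx] / h) ** 3) ** 3
            # independent oracle: numpy polyfit with sqrt-weights
            coef = np.polyfit(x[idx] - x[i], y[idx], 2, w=np.sqrt(w))
            expect[i] = coef[-1]
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_smooths_noise_towards_signal(self, rng):
        n = 200
        x = np.linspace(0, 4 * np.pi, n)
        y = np.sin(x) + 0.3 * rng.normal(size=n)
        sm = loess_smooth(y, x=x, span=0.15)
        assert np.mean((sm - np.sin(x)) ** 2) < np.mean((y - np.sin(x)) ** 2)
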