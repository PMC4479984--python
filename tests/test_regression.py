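"""PGLS/OLS fitting, inference conventions, model selection, covariate scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

import pstoich as ps
from conftest import random_tree


def gls_oracle(y, X, V):
    """Explicit-inverse GLS: beta, se (n-p denominator), ML loglik."""
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    resid = y - X @ beta
    n, p = X.shape
    rss = float(resid @ Vinv @ resid)
    se = np.sqrt(np.diag(rss / (n - p) * np.linalg.inv(XtVX)))
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(rss / n) + logdet + n)
    return beta, se, ll


class TestOLS:
    def test_two_points_exact(self):
        fit = ps.fit_ols([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert fit.beta[1] == pytest.approx(1.0)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.exact_fit and fit.r2 == 1.0

    def test_orthogonal_response(self):
        fit = ps.fit_ols([1.0, -2.0, 1.0], [-1.0, 0.0, 1.0])
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_star_tree(self):
        """x=(1..4), y=3+2x exactly: slope 2, intercept 1? No — y=2x+1."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 1.0 + 2.0 * x
        star = ps.parse_newick("(A:1,B:1,C:1,D:1);")
        fit = ps.fit_pgls(pd.Series(y, index=list("ABCD")),
                          pd.Series(x, index=list("ABCD"), name="x"),
                          star, lambda_mode=0.0)
        assert fit.beta[1] == pytest.approx(2.0)
        assert fit.beta[0] == pytest.approx(1.0)
        assert fit.exact_fit

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            ps.fit_ols(rng.normal(size=10), X)


class TestPGLS:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(8, seed + 50, unit_depth=False)
        C = ps.vcv_from_tree(tree)
        lam = rng.uniform(0, 1)
        Vl = ps.lambda_transform(C, lam).values
        y = rng.normal(size=8)
        x = rng.normal(size=8)
        fit = ps.fit_pgls(pd.Series(y, index=C.labels),
                          pd.DataFrame({"x": x}, index=C.labels),
                          tree, lambda_mode=lam)
        X = np.column_stack([np.ones(8), x])
        beta, se, ll = gls_oracle(y, X, Vl)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-9)
        np.testing.assert_allclose(fit.se, se, atol=1e-9)
        assert fit.loglik == pytest.approx(ll, abs=1e-9)

    def test_hand_computed_three_taxon(self, three_tip_tree, rng):
        C = ps.vcv_from_tree(three_tip_tree).values
        y = rng.normal(size=3)
        x = rng.normal(size=3)
        fit = ps.fit_pgls(pd.Series(y, index=list("ABC")),
                          pd.DataFrame({"x": x}, index=list("ABC")),
                          three_tip_tree, lambda_mode=1.0)
        X = np.column_stack([np.ones(3), x])
        Cinv = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Cinv @ X, X.T @ Cinv @ y)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)

    def test_ols_equals_pgls_lambda0_on_ultrametric_tree(self):
        """OLS is PGLS nested at lambda=0 (star phylogeny)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tree = random_tree(20, seed + 80)
            df = ps.simulate_regression_dataset(tree, (0.5, 1.5), 0.5, 1.0, rng=rng)
            pg = ps.fit_pgls(df["y"], df[["x"]], tree, lambda_mode=0.0)
            ol = ps.fit_ols(df["y"], df[["x"]])
            np.testing.assert_allclose(pg.beta, ol.beta, rtol=0, atol=1e-12)
            np.testing.assert_allclose(pg.se, ol.se, rtol=0, atol=1e-12)
            assert pg.r2 == pytest.approx(ol.r2, abs=1e-12)
            assert pg.loglik == pytest.approx(ol.loglik, abs=1e-9)

    def test_pgls_ml_loglik_dominates_ols(self):
        for seed in range(5):
            rng = np.random.default_rng(seed + 7)
            tree = random_tree(30, seed + 90)
            df = ps.simulate_regression_dataset(tree, (0.0, 1.0), 0.8, 1.0, rng=rng)
            pg = ps.fit_pgls(df["y"], df[["x"]], tree, lambda_mode="ML")
            ol = ps.fit_ols(df["y"], df[["x"]])
            assert pg.loglik >= ol.loglik - 1e-8

    def test_slope_recovery(self):
        """y = 1 + 2x + MVN(0, C_0.7): slope estimates center on 2."""
        slopes = []
        rng = np.random.default_rng(99)
        tree = random_tree(100, 17)
        for _ in range(40):
            df = ps.simulate_regression_dataset(tree, (1.0, 2.0), 0.7, 1.0, rng=rng)
            slopes.append(ps.fit_pgls(df["y"], df[["x"]], tree, "ML").slope)
        assert 1.9 <= np.mean(slopes) <= 2.1

    def test_unmatched_species_error(self, three_tip_tree):
        y = pd.Series([1.0, 2.0], index=["X", "Y"])
        with pytest.raises(ValueError, match="matched"):
            ps.fit_pgls(y, pd.DataFrame({"x": [1.0, 2.0]}, index=["X", "Y"]),
                        three_tip_tree)


class TestAdjustedR2:
    def test_formula_cases(self):
        assert ps.adjusted_r2(0.5, 99, 1) == pytest.approx(0.49485, abs=5e-6)
        assert ps.adjusted_r2(1.0, 10, 2) == 1.0
        assert ps.adjusted_r2(0.0, 10, 1) == pytest.approx(-0.125)

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            ps.adjusted_r2(0.5, 3, 2)

    @given(r2=st.floats(0.01, 0.99), n=st.integers(5, 500), p=st.integers(1, 3))
    @settings(max_examples=100, derandomize=True)
    def test_penalty_property(self, r2, n, p):
        if n <= p + 1:
            return
        adj = ps.adjusted_r2(r2, n, p)
        assert adj < r2 <= 1.0


class TestCompareModels:
    def test_identical_likelihoods_prefer_ols(self):
        a = _dummy_fit(loglik=-50.0)
        b = _dummy_fit(loglik=-50.0, kind="OLS")
        comp = ps.compare_models(a, b)
        assert comp.lrt_statistic == 0.0 and comp.p == 1.0
        assert comp.preferred == "OLS"

    def test_chi2_tail(self):
        comp = ps.compare_models(_dummy_fit(-50.0), _dummy_fit(-54.0, kind="OLS"))
        assert comp.lrt_statistic == pytest.approx(8.0)
        assert comp.p == pytest.approx(chi2.sf(8.0, 1), abs=1e-12)
        assert comp.p == pytest.approx(0.0047, abs=5e-4)
        assert comp.preferred == "PGLS"

    def test_species_mismatch(self):
        a = _dummy_fit(-50.0, species=("A", "B", "C", "D", "E"))
        b = _dummy_fit(-51.0, species=("A", "B", "C", "D", "F"), kind="OLS")
        with pytest.raises(ValueError, match="species"):
            ps.compare_models(a, b)

    def test_pgls_preferred_under_strong_signal(self):
        rng = np.random.default_rng(5)
        tree = random_tree(100, 55)
        wins = 0
        reps = 30
        for _ in range(reps):
            df = ps.simulate_regression_dataset(tree, (1.0, 2.0), 0.8, 1.0, rng=rng)
            pg = ps.fit_pgls(df["y"], df[["x"]], tree, "ML")
            ol = ps.fit_ols(df["y"], df[["x"]])
            wins += ps.compare_models(pg, ol).preferred == "PGLS"
        assert wins / reps >= 0.8


def _dummy_fit(loglik, kind="PGLS-ML-lambda", species=("A", "B", "C", "D", "E")):
    n = len(species)
    return ps.RegressionFit(
        model_kind=kind, lambda_used=0.5 if kind.startswith("PGLS") else 0.0,
        predictor_names=("x",), beta=np.array([0.0, 1.0]),
        se=np.array([1.0, 1.0]), t_stats=np.array([0.0, 1.0]),
        p_values=np.array([1.0, 0.3]), sigma2_hat=1.0, loglik=loglik,
        r2=0.1, adj_r2=0.08, n=n, df_resid=n - 2, species=tuple(species),
    )


class TestCovariateScan:
    def test_empty(self, three_tip_tree):
        tree = random_tree(10, 60)
        rng = np.random.default_rng(1)
        y = ps.simulate_traits(tree, 0.5, 1.0, 0.0, rng=rng)
        scan = ps.covariate_scan(y, pd.DataFrame(index=y.index), tree)
        assert scan.fits == () and scan.summary.empty

    def test_self_covariate_perfect_fit(self):
        tree = random_tree(10, 61)
        rng = np.random.default_rng(2)
        y = ps.simulate_traits(tree, 0.5, 1.0, 0.0, rng=rng)
        scan = ps.covariate_scan(y, pd.DataFrame({"self": y}), tree)
        fit = scan.fits[0]
        assert fit.slope == pytest.approx(1.0) and fit.r2 == pytest.approx(1.0)

    def test_true_covariate_ranks_first(self):
        """With one truly associated covariate among noise, it wins the scan."""
        rng = np.random.default_rng(77)
        tree = random_tree(99, 62)
        hits = 0
        reps = 15
        for _ in range(reps):
            _, table = ps.generate_study_like_dataset(
                ps.SimConfig(seed=int(rng.integers(2**31 - 1)))
            )
            signal = ps.simulate_traits(tree, 0.5, 1.0, 0.0, rng=rng)
            covs = pd.DataFrame(
                {f"c{i}": rng.standard_normal(99) for i in range(9)},
                index=signal.index,
            )
            covs["true"] = 0.8 * signal + 0.3 * rng.standard_normal(99)
            hits += ps.covariate_scan(signal, covs, tree).summary.iloc[0]["covariate"] == "true"
        assert hits / reps >= 0.8
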