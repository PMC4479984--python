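"""Synthetic tree and trait generator: structure, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

import pstoich as ps


class TestSimulateTree:
    def test_yule_structure(self):
        tree = ps.simulate_tree(n_tips=5, rng=np.random.default_rng(0))
        assert tree.n_tips == 5
        internal = sum(
            1 for nd in tree._dtree.preorder_node_iter() if not nd.is_leaf()
        )
        assert internal == 4  # rooted binary: n - 1 internal nodes
        assert tree.is_ultrametric()

    def test_two_tips_is_cherry(self):
        tree = ps.simulate_tree(n_tips=2, rng=np.random.default_rng(1))
        assert tree.n_tips == 2

    def test_deterministic_under_seed(self):
        a = ps.simulate_tree(n_tips=8, rng=np.random.default_rng(7))
        b = ps.simulate_tree(n_tips=8, rng=np.random.default_rng(7))
        assert a.as_newick() == b.as_newick()

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            ps.simulate_tree(n_tips=5, birth_rate=1.0, death_rate=1.0,
                             rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            ps.SimConfig(birth_rate=0.0)

    def test_birth_death_with_extinction(self):
        tree = ps.simulate_tree(n_tips=10, birth_rate=1.0, death_rate=0.5,
                                rng=np.random.default_rng(3))
        assert tree.n_tips == 10
        assert tree.is_ultrametric()

    def test_unit_depth_scaling(self):
        tree = ps.simulate_tree(n_tips=20, rng=np.random.default_rng(4),
                                unit_depth=True)
        depths = np.array(list(tree.tip_depths().values()))
        np.testing.assert_allclose(depths, 1.0, rtol=1e-9)


class TestSimulateTraits:
    def test_deterministic(self):
        tree = ps.simulate_tree(n_tips=10, rng=np.random.default_rng(5))
        a = ps.simulate_traits(tree, 0.5, 1.0, 2.0, rng=np.random.default_rng(9))
        b = ps.simulate_traits(tree, 0.5, 1.0, 2.0, rng=np.random.default_rng(9))
        pd.testing.assert_series_equal(a, b)

    def test_zero_variance_limit(self):
        tree = ps.simulate_tree(n_tips=6, rng=np.random.default_rng(6))
        vals = ps.simulate_traits(tree, 0.7, 0.0, 3.5, rng=np.random.default_rng(0))
        assert (vals == 3.5).all()

    def test_lambda0_iid_variance(self):
        """At lambda=0 tips are independent Normal(mean, sigma^2 * depth)."""
        tree = ps.simulate_tree(n_tips=5, rng=np.random.default_rng(8),
                                unit_depth=True)
        rng = np.random.default_rng(10)
        draws = np.array([
            ps.simulate_traits(tree, 0.0, 2.0, 1.0, rng=rng).to_numpy()
            for _ in range(2000)
        ])
        var = draws.var(axis=0, ddof=1)
        np.testing.assert_allclose(var, 2.0, rtol=0.12)
        np.testing.assert_allclose(draws.mean(axis=0), 1.0, atol=0.12)
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1

    def test_empirical_covariance_matches_lambda_vcv(self):
        """Tip covariance over replicates reproduces sigma^2 * C_lambda."""
        tree = ps.simulate_tree(n_tips=5, rng=np.random.default_rng(12),
                                unit_depth=True)
        lam, s2 = 0.6, 1.5
        target = s2 * ps.lambda_transform(ps.vcv_from_tree(tree), lam).values
        rng = np.random.default_rng(13)
        draws = np.array([
            ps.simulate_traits(tree, lam, s2, 0.0, rng=rng).to_numpy()
            for _ in range(2000)
        ])
        emp = np.cov(draws.T)
        np.testing.assert_allclose(emp, target, atol=0.1 * np.max(target))


class TestRegressionDataset:
    def test_exact_linear_when_noiseless(self):
        tree = ps.simulate_tree(n_tips=20, rng=np.random.default_rng(14))
        df = ps.simulate_regression_dataset(tree, (1.0, 2.0), 0.5, 0.0,
                                            rng=np.random.default_rng(2))
        np.testing.assert_allclose(df["y"], 1.0 + 2.0 * df["x"], rtol=1e-12)
        assert ps.fit_ols(df["y"], df[["x"]]).r2 == 1.0

    def test_null_slope_type_one_error(self):
        """beta1 = 0: PGLS slope test rejects at roughly the nominal rate."""
        tree = ps.simulate_tree(n_tips=100, rng=np.random.default_rng(15),
                                unit_depth=True)
        rng = np.random.default_rng(16)
        reps, rej = 200, 0
        for _ in range(reps):
            df = ps.simulate_regression_dataset(tree, (1.0, 0.0), 0.7, 1.0, rng=rng)
            fit = ps.fit_pgls(df["y"], df[["x"]], tree, "ML")
            rej += fit.p_values[1] < 0.05
        assert 0.005 <= rej / reps <= 0.10


class TestStudyLikeDataset:
    def test_schema(self):
        _, table = ps.generate_study_like_dataset(ps.SimConfig(seed=0))
        expected = {"2C", "C", "N", "P", "C:N", "N:P", "C:P"} | {
            f"bio{i}" for i in range(1, 20)
        }
        assert expected == set(table.columns)
        assert len(table) == 99

    def test_ratios_exact(self):
        _, table = ps.generate_study_like_dataset(ps.SimConfig(seed=1))
        np.testing.assert_array_equal(table["N:P"], table["N"] / table["P"])
        np.testing.assert_array_equal(table["C:N"], table["C"] / table["N"])
        np.testing.assert_array_equal(table["C:P"], table["C"] / table["P"])

    def test_determinism(self):
        t1, a = ps.generate_study_like_dataset(ps.SimConfig(seed=3))
        t2, b = ps.generate_study_like_dataset(ps.SimConfig(seed=3))
        assert t1.as_newick() == t2.as_newick()
        pd.testing.assert_frame_equal(a, b)

    def test_leaf_n_summary_near_targets(self):
        """Mean/SD of simulated leaf N within 15% of the configured targets
        over the default seed set."""
        means, sds = [], []
        for seed in range(8):
            _, table = ps.generate_study_like_dataset(ps.SimConfig(seed=seed))
            means.append(table["N"].mean())
            sds.append(table["N"].std(ddof=1))
        assert abs(np.mean(means) - 14.65) / 14.65 < 0.15
        assert abs(np.mean(sds) - 5.78) / 5.78 < 0.15

    def test_lambda_recovery_end_to_end(self):
        """Signal estimated from the generated leaf N is near the generating
        strength (mixture of the latitude axis and the N-specific field)."""
        tree, table = ps.generate_study_like_dataset(ps.SimConfig(seed=5))
        fit = ps.estimate_lambda(table["N"], tree)
        assert abs(fit.lambda_hat - 0.77) <= 0.15

    def test_infeasible_targets(self):
        with pytest.raises(ValueError, match="SD"):
            ps.SimConfig(trait_sds={"N": -1.0})

    def test_fixture_roundtrip(self, tmp_path):
        paths = ps.write_fixture(tmp_path, ps.SimConfig(seed=2, n_tips=20))
        tree = ps.read_newick(paths["tree"])
        table = ps.read_trait_table(paths["traits"])
        assert tree.n_tips == 20 and len(table) == 20
        assert set(tree.tip_labels) == set(table.index)
        import yaml

        cfg = yaml.safe_load(open(paths["config"]))
        assert cfg["seed"] == 2 and cfg["n_tips"] == 20
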