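"""Calibration and parameter-recovery experiments.

Self-contained simulation studies that measure how well the estimators
recover known generating parameters: agreement of the whitened GLS
likelihood with a brute-force multivariate-normal density, exact nesting of
OLS inside PGLS at lambda = 0, bias of the lambda ML estimate across the
signal range, type-I error of the boundary LRT, slope recovery under
phylogenetically correlated residuals, and the power of the PGLS-vs-OLS
model comparison.  Each function takes an explicit ``numpy.random.Generator``
and returns plain floats/dicts, so results are reproducible and reportable.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal

from . import regression, signal, simulate, tree as tree_mod

__all__ = [
    "oracle_loglik_max_error",
    "nesting_max_error",
    "lambda_recovery",
    "lambda_lrt_type_one_error",
    "slope_recovery",
    "pgls_preference_rate",
    "branch_scaling_max_error",
]


def _brute_force_loglik(y, X, V):
    """Maximized MVN log-density via explicit inverse and determinant."""
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    sigma2 = float((y - X @ beta) @ Vinv @ (y - X @ beta)) / y.size
    return multivariate_normal(mean=X @ beta, cov=sigma2 * V).logpdf(y)


def oracle_loglik_max_error(n_instances: int, rng: np.random.Generator) -> float:
    """Max |whitened GLS loglik - brute-force MVN loglik| over random
    instances with 4-8 taxa, random designs and random lambda."""
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(4, 9))
        t = simulate.simulate_tree(n_tips=n, rng=rng)
        C = tree_mod.vcv_from_tree(t)
        lam = float(rng.uniform())
        y = rng.normal(size=n)
        p = int(rng.integers(1, 3))
        X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
        ours = signal.gls_profile_loglik(y, X, C.values, lam).value
        Vl = tree_mod.lambda_transform(C, lam).values
        worst = max(worst, abs(ours - _brute_force_loglik(y, X, Vl)))
    return worst


def nesting_max_error(n_datasets: int, rng: np.random.Generator) -> float:
    """Max |PGLS(lambda fixed 0) - OLS| over coefficients and their SEs on
    random ultrametric-tree datasets."""
    import pandas as pd

    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(10, 40))
        t = simulate.simulate_tree(n_tips=n, rng=rng, unit_depth=True)
        df = simulate.simulate_regression_dataset(
            t, (rng.normal(), rng.normal()), float(rng.uniform()), 1.0, rng=rng
        )
        pg = regression.fit_pgls(df["y"], df[["x"]], t, lambda_mode=0.0)
        ol = regression.fit_ols(df["y"], df[["x"]])
        worst = max(
            worst,
            float(np.max(np.abs(pg.beta - ol.beta))),
            float(np.max(np.abs(pg.se - ol.se))),
        )
    return worst


def lambda_recovery(
    lambdas, n_replicates: int, n_tips: int, rng: np.random.Generator
) -> dict[float, float]:
    """Mean lambda-hat per true lambda, fresh Yule tree per replicate."""
    out = {}
    for lam in lambdas:
        est = []
        for _ in range(n_replicates):
            t = simulate.simulate_tree(n_tips=n_tips, rng=rng, unit_depth=True)
            y = simulate.simulate_traits(t, float(lam), 1.0, 0.0, rng=rng)
            est.append(signal.estimate_lambda(y, t).lambda_hat)
        out[float(lam)] = float(np.mean(est))
    return out


def lambda_lrt_type_one_error(
    n_replicates: int, n_tips: int, rng: np.random.Generator, alpha: float = 0.05
) -> float:
    """Rejection rate of H0: lambda = 0 on data truly generated at lambda = 0.

    The null sits on the parameter boundary, so the chi-square(1) reference
    is conservative; rates land below the nominal level.
    """
    t = simulate.simulate_tree(n_tips=n_tips, rng=rng, unit_depth=True)
    rejections = 0
    for _ in range(n_replicates):
        y = simulate.simulate_traits(t, 0.0, 1.0, 0.0, rng=rng)
        rejections += signal.estimate_lambda(y, t).p_vs_0 < alpha
    return rejections / n_replicates


def slope_recovery(
    n_replicates: int,
    n_tips: int,
    rng: np.random.Generator,
    beta=(1.0, 2.0),
    lambda_resid: float = 0.7,
) -> float:
    """Mean ML-lambda PGLS slope when y = b0 + b1 x + MVN(0, C_lambda)."""
    t = simulate.simulate_tree(n_tips=n_tips, rng=rng, unit_depth=True)
    slopes = []
    for _ in range(n_replicates):
        df = simulate.simulate_regression_dataset(t, beta, lambda_resid, 1.0, rng=rng)
        slopes.append(regression.fit_pgls(df["y"], df[["x"]], t, "ML").slope)
    return float(np.mean(slopes))


def pgls_preference_rate(
    n_replicates: int,
    n_tips: int,
    rng: np.random.Generator,
    lambda_resid: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates in which the LRT prefers PGLS over OLS when the
    residuals really are phylogenetically structured."""
    t = simulate.simulate_tree(n_tips=n_tips, rng=rng, unit_depth=True)
    wins = 0
    for _ in range(n_replicates):
        df = simulate.simulate_regression_dataset(t, (1.0, 2.0), lambda_resid, 1.0, rng=rng)
        pg = regression.fit_pgls(df["y"], df[["x"]], t, "ML")
        ol = regression.fit_ols(df["y"], df[["x"]])
        wins += regression.compare_models(pg, ol, alpha=alpha).preferred == "PGLS"
    return wins / n_replicates


def branch_scaling_max_error(
    n_trees: int, rng: np.random.Generator, lambdas=(0.0, 0.25, 0.5, 0.75, 1.0)
) -> float:
    """Max entrywise gap between the off-diagonal lambda rescaling and the
    internal-branch-scaling construction on ultrametric trees.

    The two constructions coincide on ultrametric trees: multiplying every
    internal branch by lambda while stretching tip branches to keep each
    root-to-tip depth fixed yields exactly the matrix with off-diagonals
    scaled by lambda.
    """
    worst = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(5, 25))
        t = simulate.simulate_tree(n_tips=n, rng=rng, unit_depth=True)
        C = tree_mod.vcv_from_tree(t)
        depths = t.tip_depths()
        for lam in lambdas:
            direct = tree_mod.lambda_transform(C, lam).values
            scaled = _scale_internal_branches_vcv(t, lam, depths)
            worst = max(worst, float(np.max(np.abs(direct - scaled))))
    return worst


def _scale_internal_branches_vcv(t: tree_mod.PhyloTree, lam: float, depths) -> np.ndarray:
    clone = t._dtree.clone(depth=1)
    for nd in clone.preorder_node_iter():
        if nd is clone.seed_node or nd.is_leaf():
            continue
        nd.edge.length *= lam
    for leaf in clone.leaf_node_iter():
        d = 0.0
        anc = leaf.parent_node
        while anc is not None:
            d += anc.edge.length or 0.0
            anc = anc.parent_node
        leaf.edge.length = depths[str(leaf.taxon.label).strip()] - d
    return tree_mod.vcv_from_tree(tree_mod.PhyloTree(clone)).values
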