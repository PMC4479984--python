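"""PGLS and OLS regression with likelihood-ratio model selection.

PGLS is generalized least squares whose residual covariance is proportional
to the lambda-scaled phylogenetic matrix ``C_lambda``; OLS is the special
case lambda = 0 on a star phylogeny (all species equally unrelated).  The
regression of interest here is genome size (2C DNA content, pg) on leaf
nutrient traits, but the machinery is generic.

Conventions (documented in docs/methods.md):

* ``sigma2_hat`` for coefficient standard errors uses the ``n - p``
  denominator; the ML variance (denominator ``n``) appears only inside
  log-likelihoods, so that the PGLS/OLS likelihood-ratio test compares true
  maximized likelihoods.
* R-squared for a GLS fit is defined against the GLS intercept-only model at
  the same lambda: ``1 - RSS_lambda / TSS_lambda`` with both sums of squares
  in the Mahalanobis metric of ``C_lambda``.  At lambda = 0 this reduces to
  the ordinary R-squared.
* Model comparison PGLS (ML lambda) vs OLS is a likelihood-ratio test with
  one degree of freedom (the lambda parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .signal import _ProfileCache, _gls_solve, _profile_loglik_from_parts, lrt
from .tree import PhyloTree, prune_to_taxa, vcv_from_tree

__all__ = [
    "RegressionFit",
    "ModelComparison",
    "CovariateScan",
    "fit_pgls",
    "fit_ols",
    "adjusted_r2",
    "compare_models",
    "covariate_scan",
]

_EXACT_FIT_TOL = 1e-12


@dataclass(frozen=True)
class RegressionFit:
    """A fitted PGLS or OLS regression.

    ``beta`` holds the intercept first, then one slope per predictor, in
    response units per predictor unit.  ``p_values`` are two-sided t tests
    on ``df_resid`` degrees of freedom.
    """

    model_kind: str  # "PGLS-ML-lambda" | "PGLS-fixed-lambda" | "OLS"
    lambda_used: float
    predictor_names: tuple[str, ...]
    beta: np.ndarray = field(repr=False)
    se: np.ndarray = field(repr=False)
    t_stats: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    sigma2_hat: float
    loglik: float
    r2: float
    adj_r2: float
    n: int
    df_resid: int
    species: tuple[str, ...] = field(repr=False, default=())
    exact_fit: bool = False
    n_dropped: int = 0

    @property
    def slope(self) -> float:
        """First slope coefficient (convenience for single-predictor fits)."""
        return float(self.beta[1])

    def summary_row(self) -> dict:
        return {
            "model": self.model_kind,
            "lambda": self.lambda_used,
            "intercept": float(self.beta[0]),
            "slope": float(self.beta[1]) if self.beta.size > 1 else np.nan,
            "se": float(self.se[1]) if self.se.size > 1 else np.nan,
            "t": float(self.t_stats[1]) if self.t_stats.size > 1 else np.nan,
            "p": float(self.p_values[1]) if self.p_values.size > 1 else np.nan,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "loglik": self.loglik,
            "n": self.n,
        }


@dataclass(frozen=True)
class ModelComparison:
    """LRT between a PGLS fit (ML lambda) and its OLS special case."""

    loglik_pgls: float
    loglik_ols: float
    lrt_statistic: float
    df: int
    p: float
    preferred: str  # "PGLS" | "OLS"
    alpha: float = 0.05


@dataclass(frozen=True)
class CovariateScan:
    """Per-covariate single-predictor PGLS fits plus a p-sorted summary."""

    fits: tuple[RegressionFit, ...]
    summary: pd.DataFrame


def adjusted_r2(r2: float, n: int, p_predictors: int) -> float:
    """Adjusted R-squared: ``1 - (1 - R^2)(n - 1)/(n - p - 1)``.

    May be negative for weak fits; equals R-squared only when R-squared is 1.
    """
    if n <= p_predictors + 1:
        raise ValueError(f"need n > p + 1, got n={n}, p={p_predictors}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_predictors - 1)


def _prepare(y, X, tree: PhyloTree | None):
    """Align response, predictors and tree; listwise-delete missing values.

    Returns (y_vec, X_mat_with_intercept, names, species, C_or_None, n_dropped).
    """
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        names = tuple(map(str, X.columns))
    elif X is None:
        names = ()
        X = pd.DataFrame(index=getattr(y, "index", None))
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[0] == 1 and np.size(y) > 1:
            arr = arr.T
        names = tuple(f"x{i+1}" for i in range(arr.shape[1]))
        X = pd.DataFrame(arr, columns=list(names))

    if isinstance(y, (pd.Series, dict)):
        y = pd.Series(y, dtype=float)
        df = X.astype(float).copy()
        df.insert(0, "__y__", y)
    else:
        yv = np.asarray(y, dtype=float).ravel()
        df = X.astype(float).copy()
        df.index = range(len(yv)) if len(df) == len(yv) else df.index
        df.insert(0, "__y__", yv)
    df.index = [str(i).strip() for i in df.index]
    if tree is not None and len(df) == tree.n_tips and set(df.index).isdisjoint(tree.tip_labels):
        # unlabelled arrays are taken as aligned to the sorted tip labels
        df.index = list(tree.tip_labels)

    n_before = len(df)
    df = df.dropna()
    species: tuple[str, ...]
    if tree is not None:
        common = sorted(set(df.index) & set(tree.tip_labels))
        df = df.loc[common]
        species = tuple(common)
        if len(df) < len(names) + 2:
            raise ValueError(
                f"only {len(df)} species matched between data and tree "
                f"({tree.n_tips} tips, {n_before} data rows); need >= {len(names) + 2}"
            )
        if set(common) != set(tree.tip_labels):
            tree = prune_to_taxa(tree, common)
        C = vcv_from_tree(tree).values
    else:
        species = tuple(df.index)
        C = None
        if len(df) < len(names) + 2:
            raise ValueError(f"need >= {len(names) + 2} complete rows, got {len(df)}")

    yv = df["__y__"].to_numpy()
    Xm = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in X.columns])

    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        bad = []
        for j in range(1, Xm.shape[1]):
            sub = np.delete(Xm, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j - 1])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or names}")
    return yv, Xm, names, species, C, n_before - len(df)


def _finish_fit(
    model_kind, lam, names, yv, Xm, cache, species, n_dropped
) -> RegressionFit:
    n, p = Xm.shape
    # final quantities use the direct Cholesky route so that nested special
    # cases (lambda = 0 vs OLS) agree to machine precision; the eigen-based
    # cache is only a fast path for the lambda search
    Vl = lam * cache.C
    np.fill_diagonal(Vl, np.diag(cache.C))
    beta, rss, logdet = _gls_solve(yv, Xm, Vl)
    # intercept-only fit at the same lambda defines the (generalized) TSS
    _, tss, _ = _gls_solve(yv, np.ones((n, 1)), Vl)

    exact = rss <= _EXACT_FIT_TOL * max(tss, 1.0)
    if exact:
        loglik = np.inf  # variance collapses; likelihood unbounded
        sigma2_inf = 0.0
        se = np.zeros(p)
        t_stats = np.where(beta != 0.0, np.sign(beta) * np.inf, 0.0)
        p_values = np.where(np.abs(beta) > 0, 0.0, 1.0)
        r2 = 1.0
    else:
        loglik, _ = _profile_loglik_from_parts(n, rss, logdet)
        sigma2_inf = rss / (n - p)
        XtVX = Xm.T @ np.linalg.solve(Vl, Xm)
        cov = sigma2_inf * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        t_stats = beta / se
        p_values = 2.0 * t_dist.sf(np.abs(t_stats), n - p)
        r2 = 1.0 - rss / tss
    adj = adjusted_r2(r2, n, p - 1) if p > 1 else r2
    return RegressionFit(
        model_kind=model_kind,
        lambda_used=float(lam),
        predictor_names=names,
        beta=beta,
        se=se,
        t_stats=t_stats,
        p_values=np.asarray(p_values, dtype=float),
        sigma2_hat=sigma2_inf,
        loglik=float(loglik),
        r2=float(r2),
        adj_r2=float(adj),
        n=n,
        df_resid=n - p,
        species=species,
        exact_fit=bool(exact),
        n_dropped=n_dropped,
    )


def fit_pgls(y, X, tree: PhyloTree, lambda_mode="ML") -> RegressionFit:
    """Fit a phylogenetic GLS regression.

    Parameters
    ----------
    y : response — pandas Series indexed by species (or array aligned to
        sorted tip labels).
    X : predictors — DataFrame/Series indexed by species, or array.
        An intercept column is added automatically.
    tree : PhyloTree supplying the covariance structure.
    lambda_mode : "ML" to maximize the residual likelihood over lambda in
        [0, 1], or a float to fix lambda (0 reproduces OLS on an
        ultrametric tree).

    Returns
    -------
    RegressionFit (see class docstring for the inference conventions).
    """
    yv, Xm, names, species, C, n_dropped = _prepare(y, X, tree)
    cache = _ProfileCache(yv, Xm, C)
    if isinstance(lambda_mode, str):
        if lambda_mode.upper() != "ML":
            raise ValueError(f"lambda_mode must be 'ML' or a float, got {lambda_mode!r}")
        lam = _ml_lambda(cache)
        kind = "PGLS-ML-lambda"
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"fixed lambda must be in [0, 1], got {lam}")
        kind = "PGLS-fixed-lambda"
    return _finish_fit(kind, lam, names, yv, Xm, cache, species, n_dropped)


def _ml_lambda(cache: _ProfileCache, grid_size: int = 21) -> float:
    from scipy import optimize

    grid = np.linspace(0.0, 1.0, grid_size)
    ll = np.array([cache.loglik(g) for g in grid])
    k = int(np.argmax(ll))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid_size - 1)]
    best_lam, best_ll = float(grid[k]), float(ll[k])
    res = optimize.minimize_scalar(
        lambda lam: -cache.loglik(lam), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun > best_ll:
        best_lam, best_ll = float(res.x), float(-res.fun)
    for cand in (0.0, 1.0):
        cll = cache.loglik(cand)
        if cll > best_ll:
            best_lam, best_ll = cand, cll
    return best_lam


def fit_ols(y, X) -> RegressionFit:
    """Ordinary least squares: PGLS under a star phylogeny (identity C)."""
    yv, Xm, names, species, _, n_dropped = _prepare(y, X, tree=None)
    C = np.eye(len(yv))
    cache = _ProfileCache(yv, Xm, C)
    fit = _finish_fit("OLS", 0.0, names, yv, Xm, cache, species, n_dropped)
    return fit


def compare_models(fit_pgls_ml: RegressionFit, fit_ols_: RegressionFit, alpha: float = 0.05) -> ModelComparison:
    """LRT of PGLS (ML lambda) against OLS; df = 1 for the lambda parameter.

    PGLS is preferred iff p < alpha (OLS is nested at lambda = 0, so the
    statistic is non-negative up to optimizer tolerance).
    """
    if fit_pgls_ml.species and fit_ols_.species and set(fit_pgls_ml.species) != set(fit_ols_.species):
        raise ValueError(
            f"species sets differ between fits "
            f"({fit_pgls_ml.n} vs {fit_ols_.n} species)"
        )
    res = lrt(fit_pgls_ml.loglik, fit_ols_.loglik, df=1)
    preferred = "PGLS" if res.p < alpha else "OLS"
    return ModelComparison(
        loglik_pgls=fit_pgls_ml.loglik,
        loglik_ols=fit_ols_.loglik,
        lrt_statistic=res.statistic,
        df=res.df,
        p=res.p,
        preferred=preferred,
        alpha=alpha,
    )


def covariate_scan(y, covariates: pd.DataFrame, tree: PhyloTree) -> CovariateScan:
    """Single-predictor PGLS (ML lambda) of ``y`` on each covariate.

    Mirrors screening a panel of bioclimatic variables against a leaf
    nutrient: each covariate is fit separately and the summary table is
    sorted by the slope's p-value.  No multiple-testing correction is
    applied; the p-values are raw.
    """
    fits: list[RegressionFit] = []
    rows = []
    for name in covariates.columns:
        fit = fit_pgls(y, covariates[[name]], tree, lambda_mode="ML")
        fits.append(fit)
        row = fit.summary_row()
        row["covariate"] = str(name)
        rows.append(row)
    if not rows:
        return CovariateScan(fits=(), summary=pd.DataFrame(
            columns=["covariate", "lambda", "slope", "se", "t", "p", "r2", "adj_r2", "loglik", "n"]
        ))
    summary = pd.DataFrame(rows)[
        ["covariate", "lambda", "slope", "se", "t", "p", "r2", "adj_r2", "loglik", "n"]
    ].sort_values("p", kind="mergesort").reset_index(drop=True)
    return CovariateScan(fits=tuple(fits), summary=summary)
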