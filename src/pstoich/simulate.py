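"""Synthetic phylogenies and trait data with known generating parameters.

Every stage of the comparative pipeline is testable against data whose true
lambda, slope and variance are known.  The generator emulates the structure
of a karst-plant stoichiometry study: ~99 species on a birth-death tree,
leaf C/N/P concentrations (mg per g dry mass) with per-trait phylogenetic
signal, derived C:N / N:P / C:P ratios, genome size (2C DNA content, pg)
linearly coupled to leaf N with phylogenetically structured residuals, and a
panel of 19 bioclim-style covariates partially driven by one latent
"latitude" axis that also loads on leaf N.

All randomness flows through an explicitly passed ``numpy.random.Generator``
(or the integer seed in :class:`SimConfig`); there is no global state, and a
fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree, VCVMatrix, lambda_transform, parse_newick, vcv_from_tree

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_regression_dataset",
    "generate_study_like_dataset",
    "write_fixture",
]

logger = logging.getLogger(__name__)

# Leaf-element targets (means, SDs in mg per g dry mass; genome size in pg)
# and per-trait signal strengths used by the study-like generator.
_TRAIT_MEANS = {"2C": 1.9, "C": 357.97, "N": 14.65, "P": 1.45}
_TRAIT_SDS = {"2C": 0.35, "C": 18.39, "N": 5.78, "P": 0.78}
_TRAIT_LAMBDAS = {"C": 0.137, "N": 0.759, "P": 0.234}
_CONC_FLOOR = 0.01  # mg g^-1; concentrations are strictly positive

# Structural couplings: leaf N loads on the latent latitude axis; genome
# size is coupled to N (in SD units) with phylogenetic residuals.
_LAT_LOADING_N = 0.5
_N_2C_COUPLING = 0.55
_RESID_LAMBDA_2C = 0.9
_LAT_LAMBDA = 0.8
_N_BIOCLIM = 19
_TEMP_LOADING = 0.7  # bio1..bio11 ("temperature") load on the latitude axis


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    n_tips: int = 99
    birth_rate: float = 1.0
    death_rate: float = 0.0
    lambda_true: float = 0.759
    sigma2_true: float = 1.0
    beta_true: tuple[float, float] = (1.0, 2.0)
    trait_means: dict = field(default_factory=lambda: dict(_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(_TRAIT_SDS))

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if not 0 <= self.death_rate < self.birth_rate:
            raise ValueError("death_rate must satisfy 0 <= d < birth_rate")
        if not 0 <= self.lambda_true <= 1:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2_true <= 0:
            raise ValueError("sigma2_true must be > 0")
        for t, s in self.trait_sds.items():
            if s < 0:
                raise ValueError(f"negative SD target for trait {t!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _bd_forward(n_tips, birth, death, rng):
    """One forward birth-death run; returns node records or None on extinction.

    Nodes are dicts: parent, birth time, death time (None while alive).
    The run stops when ``n_tips`` lineages are simultaneously alive; a final
    waiting time is drawn so pendant branches have positive length.
    """
    nodes = [
        {"parent": None, "t0": 0.0, "t1": None},
        {"parent": 0, "t0": 0.0, "t1": None},
        {"parent": 0, "t0": 0.0, "t1": None},
    ]
    nodes[0]["t1"] = 0.0  # root speciates immediately
    alive = [1, 2]
    t = 0.0
    total = birth + death
    while len(alive) < n_tips:
        k = len(alive)
        t += rng.exponential(1.0 / (k * total))
        i = alive[rng.integers(k)]
        if rng.random() < birth / total:
            nodes[i]["t1"] = t
            for _ in range(2):
                nodes.append({"parent": i, "t0": t, "t1": None})
            alive.remove(i)
            alive.extend([len(nodes) - 2, len(nodes) - 1])
        else:
            nodes[i]["t1"] = t
            nodes[i]["dead"] = True
            alive.remove(i)
            if not alive:
                return None
    t_end = t + rng.exponential(1.0 / (n_tips * total))
    for i in alive:
        nodes[i]["t1"] = t_end
    return nodes, alive


def simulate_tree(config=None, *, n_tips=None, birth_rate=None, death_rate=None,
                  rng=None, unit_depth=False) -> PhyloTree:
    """Simulate a rooted binary tree with exactly ``n_tips`` tips.

    A conditioned-on-n forward birth-death process (Yule when the death rate
    is 0): lineages wait exponential times, split or die, and runs that go
    extinct are restarted.  The result is ultrametric with positive branch
    lengths; tips are labelled ``t001, t002, ...`` in a deterministic order.

    Accepts either a :class:`SimConfig` or keyword overrides.  With
    ``unit_depth=True`` branch lengths are rescaled so the root-to-tip depth
    is exactly 1 (convenient for interpreting sigma^2 per unit depth).
    """
    if config is None:
        config = SimConfig()
    if isinstance(config, int):
        config = SimConfig(n_tips=config)
    n = n_tips if n_tips is not None else config.n_tips
    b = birth_rate if birth_rate is not None else config.birth_rate
    d = death_rate if death_rate is not None else config.death_rate
    if n < 2:
        raise ValueError("n_tips must be >= 2")
    if b <= 0 or not 0 <= d < b:
        raise ValueError(f"invalid rates: birth={b}, death={d}")
    if rng is None:
        rng = config.rng()

    result = None
    while result is None:
        result = _bd_forward(n, b, d, rng)
    nodes, alive = result

    # build children map, pruning extinct subtrees and collapsing
    # single-child chains (extinctions leave unifurcations behind)
    children: dict[int, list[int]] = {}
    for i, nd in enumerate(nodes):
        if nd["parent"] is not None:
            children.setdefault(nd["parent"], []).append(i)

    alive_set = set(alive)
    labels = {tip: f"t{k+1:03d}" for k, tip in enumerate(sorted(alive))}

    def newick(i, extra):
        """Render subtree at node i; ``extra`` is collapsed ancestor length."""
        length = nodes[i]["t1"] - nodes[i]["t0"] + extra
        kids = [c for c in children.get(i, []) if _has_living(c)]
        if i in alive_set:
            return f"{labels[i]}:{length:.17g}"
        if len(kids) == 1:
            return newick(kids[0], length)
        inner = ",".join(newick(c, 0.0) for c in kids)
        return f"({inner}):{length:.17g}"

    def _has_living(i):
        if i in alive_set:
            return True
        return any(_has_living(c) for c in children.get(i, []))

    root_kids = [c for c in children[0] if _has_living(c)]
    if len(root_kids) == 1:
        # one root child's whole subtree went extinct; rerun (rare unless
        # the death rate is close to the birth rate)
        return simulate_tree(config, n_tips=n, birth_rate=b, death_rate=d,
                             rng=rng, unit_depth=unit_depth)
    text = "(" + ",".join(newick(c, 0.0) for c in root_kids) + ");"
    tree = parse_newick(text)
    if unit_depth:
        depth = next(iter(tree.tip_depths().values()))
        tree = tree.scale_branches(1.0 / depth)
    return tree


def simulate_traits(tree: PhyloTree, lambda_true: float, sigma2_true: float,
                    mean: float, *, rng: np.random.Generator) -> pd.Series:
    """One trait draw from ``MVN(mean * 1, sigma^2 C_lambda)`` on the tree.

    lambda = 1 is pure Brownian motion; lambda = 0 makes tips independent
    with variance ``sigma^2 * depth_i``.  Returns a Series indexed by the
    sorted tip labels.
    """
    if sigma2_true < 0:
        raise ValueError("sigma2_true must be >= 0")
    C = lambda_transform(vcv_from_tree(tree), lambda_true)
    if sigma2_true == 0.0:
        return pd.Series(mean, index=list(C.labels))
    try:
        L = np.linalg.cholesky(sigma2_true * C.values)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"lambda-scaled covariance is singular (lambda={lambda_true}): {e}"
        ) from e
    z = rng.standard_normal(C.n)
    return pd.Series(mean + L @ z, index=list(C.labels))


def simulate_regression_dataset(tree: PhyloTree, beta_true, lambda_true: float,
                                sigma2_true: float, *, rng: np.random.Generator,
                                x_sigma2: float = 1.0) -> pd.DataFrame:
    """Predictor/response pair with a known linear relationship.

    ``x`` evolves by pure Brownian motion (lambda = 1, rate ``x_sigma2``);
    ``y = b0 + b1 x + eps`` with ``eps ~ MVN(0, sigma^2 C_lambda)``.
    Returns a DataFrame with columns ``x`` and ``y`` indexed by species.
    """
    b0, b1 = float(beta_true[0]), float(beta_true[1])
    x = simulate_traits(tree, 1.0, x_sigma2, 0.0, rng=rng)
    if sigma2_true == 0.0:
        eps = pd.Series(0.0, index=x.index)
    else:
        eps = simulate_traits(tree, lambda_true, sigma2_true, 0.0, rng=rng)
    y = b0 + b1 * x + eps
    return pd.DataFrame({"x": x, "y": y})


def _standardized_phylo_draw(chol_by_lambda, lam, rng, tree):
    """Unit-variance phylo-structured draw on a unit-depth tree (cached chol)."""
    if lam not in chol_by_lambda:
        C = lambda_transform(vcv_from_tree(tree), lam)
        chol_by_lambda[lam] = (np.linalg.cholesky(C.values), list(C.labels))
    L, labels = chol_by_lambda[lam]
    return pd.Series(L @ rng.standard_normal(len(labels)), index=labels)


def generate_study_like_dataset(config: SimConfig | None = None,
                                *, rng: np.random.Generator | None = None
                                ) -> tuple[PhyloTree, pd.DataFrame]:
    """A full study-shaped dataset: 99-tip tree + trait table.

    Columns: genome size ``2C`` (pg), leaf ``C``, ``N``, ``P`` (mg/g), the
    derived ratios ``C:N``, ``N:P``, ``C:P``, and 19 bioclim-like covariates
    ``bio1..bio19``.  Leaf N carries strong phylogenetic signal, leaf C weak;
    genome size is positively coupled to N with phylogenetically structured
    residuals, so the PGLS-vs-OLS likelihood-ratio test favors PGLS; a latent
    latitude axis drives the "temperature" covariates bio1-bio11 and part of
    leaf N.  Element concentrations are floored at 0.01 mg/g (count logged).
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = config.rng()
    tree = simulate_tree(config, rng=rng, unit_depth=True)
    chol: dict = {}

    lat = _standardized_phylo_draw(chol, _LAT_LAMBDA, rng, tree)

    means, sds = config.trait_means, config.trait_sds
    z_n = (_LAT_LOADING_N * lat
           + np.sqrt(1.0 - _LAT_LOADING_N**2)
           * _standardized_phylo_draw(chol, _TRAIT_LAMBDAS["N"], rng, tree))
    z_c = _standardized_phylo_draw(chol, _TRAIT_LAMBDAS["C"], rng, tree)
    z_p = _standardized_phylo_draw(chol, _TRAIT_LAMBDAS["P"], rng, tree)
    z_2c = (_N_2C_COUPLING * z_n
            + np.sqrt(1.0 - _N_2C_COUPLING**2)
            * _standardized_phylo_draw(chol, _RESID_LAMBDA_2C, rng, tree))

    table = pd.DataFrame(index=list(tree.tip_labels))
    table.index.name = "species"
    table["2C"] = means["2C"] + sds["2C"] * z_2c
    table["C"] = means["C"] + sds["C"] * z_c
    table["N"] = means["N"] + sds["N"] * z_n
    table["P"] = means["P"] + sds["P"] * z_p

    n_floored = 0
    for col in ("2C", "C", "N", "P"):
        low = table[col] < _CONC_FLOOR
        n_floored += int(low.sum())
        table.loc[low, col] = _CONC_FLOOR
    if n_floored:
        logger.info("floored %d trait values at %s", n_floored, _CONC_FLOOR)

    table["C:N"] = table["C"] / table["N"]
    table["N:P"] = table["N"] / table["P"]
    table["C:P"] = table["C"] / table["P"]

    for k in range(1, _N_BIOCLIM + 1):
        if k <= 11:
            noise = rng.standard_normal(len(table))
            table[f"bio{k}"] = (_TEMP_LOADING * lat.to_numpy()
                                + np.sqrt(1.0 - _TEMP_LOADING**2) * noise)
        else:
            table[f"bio{k}"] = rng.standard_normal(len(table))
    return tree, table


def write_fixture(out_dir, config: SimConfig | None = None) -> dict:
    """Write a complete fixture directory: tree.nwk + traits.csv + config.yaml.

    Returns a dict of the paths written.
    """
    import pathlib

    import yaml

    if config is None:
        config = SimConfig()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, table = generate_study_like_dataset(config)
    tree_path = out / "tree.nwk"
    tree_path.write_text(tree.as_newick() + "\n")
    traits_path = out / "traits.csv"
    table.to_csv(traits_path)
    cfg_path = out / "config.yaml"
    cfg = dataclasses.asdict(config)
    cfg["beta_true"] = list(cfg["beta_true"])
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return {"tree": str(tree_path), "traits": str(traits_path), "config": str(cfg_path)}
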