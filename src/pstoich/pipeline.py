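"""Orchestration of the full comparative analysis.

Composes the building blocks into the study workflow: descriptive statistics
of the trait table, a per-trait phylogenetic-signal table, a PGLS/OLS
regression table with likelihood-ratio model selection, and a climatic
covariate scan — all written as TSV reports plus a JSON metadata record, so
a run is reproducible from its config and seed alone.

Species in the tree and the trait table are matched by exact string equality
after trimming whitespace; unmatched species are dropped with logged counts.
Ratio columns (C:N, N:P, C:P) are derived from the element columns when
absent.  Numeric report formatting follows the conventions of comparative
studies: 3 decimals for lambda and R-squared, 2 for summary statistics,
scientific notation for p-values below 1e-3.
"""

from __future__ import annotations

import json
import logging
import pathlib
import platform
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import compare_models, covariate_scan, fit_ols, fit_pgls
from .signal import estimate_lambda
from .tree import PhyloTree, read_newick

__all__ = [
    "SummaryRow",
    "read_trait_table",
    "descriptive_stats",
    "run_signal_table",
    "run_regression_table",
    "run_full_study",
]

logger = logging.getLogger(__name__)

_RATIOS = {"C:N": ("C", "N"), "N:P": ("N", "P"), "C:P": ("C", "P")}


@dataclass(frozen=True)
class SummaryRow:
    trait: str
    n: int
    mean: float
    sd: float  # sample SD (n - 1)
    cv: float  # sd / mean
    min: float
    max: float


def read_trait_table(path) -> pd.DataFrame:
    """Read a species x trait CSV/TSV into a validated DataFrame.

    The species column is the one named ``species`` (case-insensitive) or
    else the first column; it becomes the index.  Non-numeric cells become
    missing values (a count is logged).  Duplicate species and empty files
    are errors.
    """
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: empty trait table or no trait columns")
    species_col = next(
        (c for c in df.columns if str(c).strip().lower() == "species"), df.columns[0]
    )
    df[species_col] = df[species_col].astype(str).str.strip()
    dupes = df[species_col][df[species_col].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate species rows: {sorted(dupes)}")
    df = df.set_index(species_col)
    df.index.name = "species"

    n_coerced = 0
    for col in df.columns:
        before = df[col].notna().sum()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        n_coerced += int(before - df[col].notna().sum())
    if n_coerced:
        logger.warning("%s: %d non-numeric cells treated as missing", path, n_coerced)
    return df


def ensure_ratio_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Add C:N, N:P, C:P derived from element columns when absent.

    Division by zero yields a missing value.
    """
    table = table.copy()
    for ratio, (num, den) in _RATIOS.items():
        if ratio not in table.columns and num in table.columns and den in table.columns:
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = table[num] / table[den]
            table[ratio] = vals.replace([np.inf, -np.inf], np.nan)
    return table


def descriptive_stats(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait summary: n, mean, sample SD, CV (= SD/mean), min, max.

    Missing values are excluded per trait; all-missing columns are skipped
    with a warning.  Needs >= 2 non-missing values per reported trait.
    """
    traits = list(traits) if traits is not None else list(table.columns)
    rows = []
    for trait in traits:
        vals = pd.to_numeric(table[trait], errors="coerce").dropna()
        if len(vals) == 0:
            logger.warning("trait %r is all-missing; skipped", trait)
            continue
        if len(vals) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows.append(SummaryRow(
            trait=str(trait), n=len(vals), mean=mean, sd=sd,
            cv=sd / mean if mean != 0 else np.nan,
            min=float(vals.min()), max=float(vals.max()),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def _match(tree: PhyloTree, table: pd.DataFrame) -> tuple[PhyloTree, pd.DataFrame]:
    common = sorted(set(tree.tip_labels) & {str(i).strip() for i in table.index})
    dropped_tree = tree.n_tips - len(common)
    dropped_table = len(table) - len(common)
    if dropped_tree or dropped_table:
        logger.info("species matching dropped %d tree tips and %d table rows",
                    dropped_tree, dropped_table)
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} species shared between tree ({tree.n_tips} tips) "
            f"and table ({len(table)} rows)"
        )
    from .tree import prune_to_taxa

    if len(common) != tree.n_tips:
        tree = prune_to_taxa(tree, common)
    return tree, table.loc[common]


def run_signal_table(tree: PhyloTree, table: pd.DataFrame, traits) -> pd.DataFrame:
    """Pagel's lambda per trait: n, lambda, lnL, LRT p vs 0 and vs 1."""
    tree, table = _match(tree, table)
    rows = []
    for trait in traits:
        if trait not in table.columns:
            raise KeyError(f"trait {trait!r} not in table")
        fit = estimate_lambda(table[trait], tree)
        rows.append({
            "trait": str(trait), "n": fit.n, "lambda": fit.lambda_hat,
            "loglik": fit.loglik, "p_vs_0": fit.p_vs_0, "p_vs_1": fit.p_vs_1,
        })
    return pd.DataFrame(rows)


def run_regression_table(tree: PhyloTree, table: pd.DataFrame, response: str,
                         predictors, alpha: float = 0.05) -> pd.DataFrame:
    """PGLS (ML lambda) and OLS of ``response`` on each predictor, with LRT.

    One row per (predictor, model); each pair of rows carries the PGLS-vs-OLS
    likelihood-ratio p-value and which model it prefers at ``alpha``.
    """
    tree, table = _match(tree, table)
    if response not in table.columns:
        raise KeyError(f"response {response!r} not in table")
    rows = []
    for pred in predictors:
        if pred not in table.columns:
            raise KeyError(f"predictor {pred!r} not in table")
        cols = [response] if pred == response else [response, pred]
        sub = table[cols].dropna()
        if sub[pred].notna().sum() == 0:
            logger.warning("predictor %r all-missing; skipped", pred)
            continue
        pg = fit_pgls(sub[response], sub[[pred]], tree, lambda_mode="ML")
        ol = fit_ols(sub[response], sub[[pred]])
        comp = compare_models(pg, ol, alpha=alpha)
        for fit in (pg, ol):
            row = fit.summary_row()
            row.update({
                "response": response, "predictor": str(pred),
                "lrt_p_pgls_vs_ols": comp.p, "preferred": comp.preferred,
                "significant": bool(row["p"] < alpha),
            })
            rows.append(row)
    cols = ["response", "predictor", "model", "lambda", "intercept", "slope",
            "se", "t", "p", "significant", "r2", "adj_r2", "loglik", "n",
            "lrt_p_pgls_vs_ols", "preferred"]
    return pd.DataFrame(rows)[cols] if rows else pd.DataFrame(columns=cols)


# -- report formatting ----------------------------------------------------

def _fmt_p(x) -> str:
    if not np.isfinite(x):
        return "NA"
    return f"{x:.2e}" if 0 < x < 1e-3 else f"{x:.3f}"


def _fmt_table(df: pd.DataFrame, three_dp=(), p_cols=(), two_dp=()) -> pd.DataFrame:
    out = df.copy()
    for c in three_dp:
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "NA")
    for c in two_dp:
        if c in out.columns:
            out[c] = out[c].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "NA")
    for c in p_cols:
        if c in out.columns:
            out[c] = out[c].map(_fmt_p)
    return out


def run_full_study(config: dict, out_dir=None) -> dict:
    """Run the whole analysis from a config mapping and write reports.

    Config keys
    -----------
    tree : path to a Newick file  (or)  simulate : SimConfig-style mapping
    traits : path to a CSV/TSV trait table (unless simulating)
    summary_traits, signal_traits : trait-name lists (default: elements+ratios)
    response : regression response column (default "2C")
    predictors : regression predictor columns (default elements+ratios)
    covariate_response, covariates : covariate-scan settings (optional)
    alpha : significance level (default 0.05)
    seed : used only when simulating
    out : output directory (overridden by ``out_dir``)

    Writes summary.tsv, signal.tsv, regression.tsv, covariate_scan.tsv,
    run_metadata.json and pstoich.log into the output directory, and returns
    the in-memory tables keyed by report name.
    """
    out = pathlib.Path(out_dir or config.get("out", "pstoich_out"))
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pstoich.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("pstoich")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        if "simulate" in config or ("tree" not in config and "traits" not in config):
            from .simulate import SimConfig, generate_study_like_dataset

            sim_kwargs = dict(config.get("simulate") or {})
            if "seed" in config and "seed" not in sim_kwargs:
                sim_kwargs["seed"] = int(config["seed"])
            sim = SimConfig(**sim_kwargs)
            tree, table = generate_study_like_dataset(sim)
            n_input = len(table)
        else:
            tree_path = pathlib.Path(config["tree"])
            if not tree_path.exists():
                raise FileNotFoundError(f"tree file not found: {tree_path}")
            traits_path = pathlib.Path(config["traits"])
            if not traits_path.exists():
                raise FileNotFoundError(f"trait table not found: {traits_path}")
            tree = read_newick(tree_path)
            table = read_trait_table(traits_path)
            n_input = len(table)
        table = ensure_ratio_columns(table)

        elements = [c for c in ("C", "N", "P", "C:N", "N:P", "C:P") if c in table.columns]
        summary_traits = config.get("summary_traits") or elements
        signal_traits = config.get("signal_traits") or elements
        response = config.get("response", "2C")
        predictors = config.get("predictors") or [c for c in ("N", "P", "C:N", "N:P", "C:P") if c in table.columns]
        alpha = float(config.get("alpha", 0.05))

        results: dict[str, pd.DataFrame] = {}
        results["summary"] = descriptive_stats(table, summary_traits)
        results["signal"] = run_signal_table(tree, table, signal_traits)
        results["regression"] = run_regression_table(tree, table, response, predictors, alpha=alpha)

        cov_cols = config.get("covariates")
        if cov_cols is None:
            cov_cols = [c for c in table.columns if str(c).startswith("bio")]
        cov_response = config.get("covariate_response", "N")
        if cov_cols and cov_response in table.columns:
            mtree, mtable = _match(tree, table)
            scan = covariate_scan(mtable[cov_response], mtable[list(cov_cols)], mtree)
            results["covariate_scan"] = scan.summary
        else:
            results["covariate_scan"] = pd.DataFrame()

        _fmt_table(results["summary"], two_dp=("mean", "sd", "cv", "min", "max")) \
            .to_csv(out / "summary.tsv", sep="\t", index=False)
        _fmt_table(results["signal"], three_dp=("lambda", "loglik"),
                   p_cols=("p_vs_0", "p_vs_1")) \
            .to_csv(out / "signal.tsv", sep="\t", index=False)
        _fmt_table(results["regression"],
                   three_dp=("lambda", "intercept", "slope", "se", "t", "r2", "adj_r2", "loglik"),
                   p_cols=("p", "lrt_p_pgls_vs_ols")) \
            .to_csv(out / "regression.tsv", sep="\t", index=False)
        _fmt_table(results["covariate_scan"],
                   three_dp=("lambda", "slope", "se", "t", "r2", "adj_r2", "loglik"),
                   p_cols=("p",)) \
            .to_csv(out / "covariate_scan.tsv", sep="\t", index=False)

        meta = {
            "seed": config.get("seed"),
            "alpha": alpha,
            "n_species_input": int(n_input),
            "n_species_analyzed": int(results["signal"]["n"].max()) if len(results["signal"]) else None,
            "response": response,
            "predictors": list(map(str, predictors)),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
        logger.info("reports written to %s", out)
        return results
    finally:
        root_logger.removeHandler(handler)
        handler.close()
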