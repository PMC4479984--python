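# pstoich

Phylogenetic comparative analysis of genome size and leaf nutrient
stoichiometry: Pagel's λ signal estimation, PGLS/OLS regression, and
likelihood-ratio model selection, with a seedable synthetic-data generator
for validating every stage.

## The scientific problem

Across related plant species, does nutrient availability shape genome size?
A natural test regresses genome size (2C DNA content, pg) on leaf nitrogen
and phosphorus concentrations (mg g⁻¹ dry mass) across species.  But species
are not independent observations: close relatives inherit similar trait
values from common ancestors, so ordinary least squares (OLS) overstates the
effective sample size whenever residuals carry phylogenetic signal.

`pstoich` implements the standard comparative-methods answer:

* **Phylogenetic signal (Pagel's λ).**  Under Brownian-motion trait
  evolution on a rooted tree with branch lengths, the expected among-species
  covariance of a trait is σ²**C**, where C<sub>ij</sub> is the shared
  root-to-MRCA branch length of species *i* and *j*.  Pagel's λ rescales the
  off-diagonal of **C** by a factor λ ∈ [0, 1]:

      C_λ = λ C + (1 − λ) diag(C)

  λ = 1 is the full Brownian expectation, λ = 0 is phylogenetic
  independence (a star phylogeny), and intermediate values interpolate.
  λ is estimated by maximizing the profiled Gaussian log-likelihood of
  *y* ~ MVN(μ**1**, σ²C_λ), and its significance is assessed with
  likelihood-ratio tests against λ = 0 and λ = 1 on a χ²₁ reference.

* **PGLS regression.**  Generalized least squares with residual covariance
  σ²C_λ (λ fixed or estimated by ML):
  β̂ = (XᵀC_λ⁻¹X)⁻¹XᵀC_λ⁻¹y.  OLS is the nested special case λ = 0, and a
  likelihood-ratio test with one degree of freedom decides which model the
  data support.

* **Covariate scans.**  Single-predictor PGLS of a trait against each of a
  panel of (bioclimatic) covariates, summarized in a p-sorted table.

* **Synthetic data.**  A conditioned-on-n birth–death tree simulator and a
  trait generator with known λ, σ² and regression slopes, including a
  99-species "study-shaped" dataset (leaf C/N/P with realistic means/SDs,
  derived C:N / N:P / C:P ratios, genome size coupled to leaf N, and 19
  bioclim-like covariates driven by a latent latitude axis).

## Worked example

```python
import numpy as np
import pstoich as ps

rng = np.random.default_rng(42)
tree = ps.simulate_tree(n_tips=99, rng=rng, unit_depth=True)
trait = ps.simulate_traits(tree, lambda_true=0.7, sigma2_true=1.0,
                           mean=15.0, rng=rng)
fit = ps.estimate_lambda(trait, tree)
print(fit.lambda_hat, fit.p_vs_0)
```

Running `python examples/01_phylogenetic_signal.py` (the same computation)
prints:

```
n species          : 99
lambda (ML)        : 0.758   (true 0.7)
log-likelihood     : -114.542
lnL at lambda=0    : -129.452
lnL at lambda=1    : -136.487
LRT p vs lambda=0  : 4.74e-08
LRT p vs lambda=1  : 0.0000
```

The ML estimate 0.758 recovers the generating signal strength 0.7 (both
LRTs reject: the trait is neither phylogenetically independent nor fully
Brownian).  `examples/02_pgls_vs_ols.py` contrasts PGLS and OLS on data with
phylogenetically structured residuals:

```
PGLS-ML-lambda   lambda=0.757 slope=1.901 +- 0.122 p=2.90e-28 adjR2=0.713 lnL=-98.40
OLS              lambda=0.000 slope=1.897 +- 0.090 p=4.91e-38 adjR2=0.819 lnL=-122.84
LRT PGLS vs OLS : statistic=48.87, p=2.73e-12 -> prefer PGLS
```

Both models recover the true slope 2, but the LRT strongly prefers PGLS —
the OLS standard error is too small because it treats relatives as
independent.  `examples/03_study_like_dataset.py` and
`examples/04_covariate_scan.py` run the full study-shaped pipeline (signal
table, regression table with model selection, climatic covariate scan).

## Command line

A thin CLI wraps the same library calls:

```bash
pstoich simulate --out fixture --seed 1          # tree.nwk + traits.csv + config.yaml
pstoich signal --tree fixture/tree.nwk --traits fixture/traits.csv
pstoich pgls   --tree fixture/tree.nwk --traits fixture/traits.csv \
               --response 2C --predictors N,P,C:N
pstoich run-study --tree fixture/tree.nwk --traits fixture/traits.csv --out reports
```

`run-study` writes `summary.tsv`, `signal.tsv`, `regression.tsv`,
`covariate_scan.tsv`, a JSON metadata record and a log file; reruns with the
same config are byte-identical.

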