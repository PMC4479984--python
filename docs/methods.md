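# Methods

## Model

A continuous trait measured once per species (a species mean) is modelled as
one draw from a multivariate normal distribution over the tips of a rooted
phylogeny with branch lengths:

    y ~ MVN(X β, σ² C_λ),       C_λ = λ C + (1 − λ) diag(C)

where C is the Brownian-motion variance–covariance matrix of the tree
(C[i,j] = shared root-to-MRCA path length; diagonal = root-to-tip depth),
λ ∈ [0, 1] is Pagel's phylogenetic-signal parameter, σ² the evolutionary
rate (trait units² per unit branch length), and X a design matrix — a
column of ones for signal estimation, intercept plus predictors for PGLS.
Assumptions inherited from this model: trait evolution is gradual and
homogeneous in rate across the tree (no Ornstein–Uhlenbeck pull, no rate
shifts), species means are measured without error, and residual deviations
from the regression line share the same phylogenetic structure as the trait.

### The λ transform and its branch-length reading

λ is defined on the covariance matrix (off-diagonals × λ, diagonal fixed).
On an **ultrametric** tree this is exactly equivalent to multiplying every
internal branch by λ and stretching each terminal branch so root-to-tip
depths are preserved; the package verifies this equivalence to 1e-12 as a
property test and in the acceptance report
(`lambda_transform_construction_max_abs_err`).  On non-ultrametric trees the
two readings differ, and the covariance form is taken as authoritative — it
is the form implemented by the standard comparative-methods software, keeps
C_λ positive semi-definite for all λ ∈ [0, 1], and needs no tip-branch
bookkeeping.  A consequence worth knowing: at λ = 0 on a non-ultrametric
tree, C_0 = diag(depths) is a *weighted* identity, so PGLS(λ=0) equals OLS
exactly only on ultrametric trees (constant depth).  All simulated trees
here are ultrametric.

The root edge length, when present in the Newick, counts toward depths.
This makes pruning exact: the covariance matrix of a pruned tree equals the
corresponding submatrix of the full tree's matrix to machine precision,
because the path from the old root to the new one is retained as the new
root's edge.

## Estimation

For fixed λ, β and σ² have closed-form ML solutions (GLS mean; Mahalanobis
residual sum of squares over n), giving the profiled log-likelihood

    lnL(λ) = −½ [ n ln 2π + n ln σ̂²(λ) + ln|C_λ| + n ].

λ̂ maximizes this over [0, 1]: a 21-point grid locates the basin, a bounded
scalar minimizer (absolute tolerance 1e-8 in λ) refines it between the
flanking grid points, and both endpoints are always candidates.  A 101-point
grid audit in the test suite confirms the optimizer never lands more than
1e-6 below the grid maximum.  Factorizations are Cholesky-based; for
ultrametric trees C_λ = λC + (1 − λ)d·I shares C's eigenvectors, so one
symmetric eigendecomposition makes each λ evaluation O(n) after rotating y
and X once — the generic Cholesky path is kept for non-ultrametric input,
and the two paths agree to 1e-9 in tests.  Final reported fits always use
the direct Cholesky route so nested special cases (λ = 0 vs OLS) agree to
machine precision.  A covariance matrix without a Cholesky factor raises an
error naming the offending λ; no jitter is ever added silently.

ML (not REML) profiling is used throughout, so likelihoods are comparable
across models and against the R tooling the field uses; the test suite
cross-validates λ̂, lnL and LRT p-values against `phytools::phylosig` and
OLS inference against `lm` when an R installation is present.

### Inference conventions

* **LRTs.**  2·ΔlnL against χ² with df = the parameter difference (df = 1
  for λ).  Differences more negative than −1e-8 are an error (non-nested
  models or a failed fit); tiny negatives from optimizer tolerance clip
  to 0.  Both boundary tests (H0: λ = 0, H0: λ = 1) use the plain χ²₁
  reference, the convention of the standard tooling.  Because the null sits
  on the boundary of [0, 1], this choice is **conservative**: at n ≈ 100 on
  birth–death trees, far fewer than half of null replicates yield λ̂ > 0,
  and the measured type-I error of the λ = 0 test is near 0.01 rather than
  the nominal 0.05 (the acceptance report computes it as
  `lambda_lrt_type1_rate`; `phytools::phylosig` behaves identically on the
  same data).  The test never over-rejects; users should simply not
  interpret its p-values as exactly calibrated.
* **Coefficient inference.**  Standard errors use σ̂² on the n − p
  denominator with two-sided t tests on n − p df; the ML σ̂² (denominator n)
  appears only inside likelihoods.
* **R² for GLS fits.**  1 − RSS_λ/TSS_λ, both in the Mahalanobis metric of
  C_λ, with TSS from the GLS intercept-only fit at the same λ; adjusted R²
  applies the usual (n−1)/(n−p−1) penalty.  At λ = 0 this reduces to the
  ordinary R².  Other R² conventions for PGLS exist; this one is used
  consistently and labelled.
* **Exact fits.**  RSS below 1e-12·TSS flags `exact_fit`: the Gaussian
  likelihood is unbounded, so lnL is reported as +inf, SEs as 0 and R² as 1.
* **Degenerate traits.**  A constant trait (or zero residual variance in
  signal estimation) raises an error rather than returning −inf.
* **Star phylogenies.**  All off-diagonals zero makes λ unidentifiable; the
  fit is reported at λ = 0 with a `flat_likelihood` flag and a warning.
* **Missing data.**  Listwise deletion per analysis; species are matched to
  the tree by exact string equality after trimming whitespace, with dropped
  counts logged.  No multiple-testing correction is applied in covariate
  scans; p-values are labelled raw.

## Synthetic data

`simulate_tree` is a forward birth–death process conditioned on the tip
count (Yule for death rate 0): lineages wait exponential times, split or go
extinct, extinct subtrees are pruned, and a final waiting interval gives
pendant branches positive length, so trees are ultrametric and binary with
exactly n tips.  `unit_depth=True` rescales to root-to-tip depth 1 so σ² is
interpretable per total tree depth.

`generate_study_like_dataset` emulates the structure of a ~99-species karst
plant stoichiometry survey.  Defaults, chosen once to mirror realistic
leaf-economics values and held fixed:

| quantity | default | units / rationale |
|---|---|---|
| tips | 99 | study-scale species count |
| leaf C mean ± SD | 357.97 ± 18.39 | mg g⁻¹; C is nearly invariant across species |
| leaf N mean ± SD | 14.65 ± 5.78 | mg g⁻¹; low-N flora |
| leaf P mean ± SD | 1.45 ± 0.78 | mg g⁻¹ |
| genome size mean ± SD | 1.9 ± 0.35 | pg (2C); ~2-fold range across species |
| λ for N / C / P fields | 0.759 / 0.137 / 0.234 | strong signal in N, weak in C |
| N–2C coupling | 0.55 | SD units; no published effect size exists, so the coupling is a free, documented parameter set to give an OLS R² near 0.3 |
| 2C residual λ | 0.9 | residuals phylogenetically structured, so the LRT prefers PGLS |
| latitude loading on N / bio1–bio11 | 0.5 / 0.7 | one latent climate axis couples leaf N to "temperature" covariates; bio12–bio19 are independent noise |

Ratios C:N, N:P, C:P are computed exactly from the element columns.
Concentrations are drawn on the raw scale and floored at 0.01 mg g⁻¹ with a
logged count — real concentration data are strictly positive and
right-skewed; the floor occasionally produces large ratio outliers, which is
faithful to the heavy-tailed ratios seen in such surveys.  What the
generator does **not** emulate: within-species sampling error, log-normal
trait skew, correlated evolution of C with N/P, OU-style bounded evolution,
spatial autocorrelation of climate beyond the single latent axis, or missing
data.  Tests passing on these data therefore show estimator correctness and
calibration under the model's own assumptions, not robustness to their
violation.

## Problem sizes

The statistical suites use the sizes at which the properties are stated:
λ recovery uses 100 replicates per true λ on 200-tip trees, type-I error 500
replicates at n = 100, slope recovery and model-preference rates 200
replicates at n = 100; smaller unit tests use 5–40 tips.  The whole test
suite and the acceptance script each complete in well under a minute on one
CPU thanks to the eigendecomposition fast path.

## Known limitations

* Single-optimum refinement: the profile likelihood of λ is usually
  unimodal but not provably so; the 21-point grid seed makes a missed global
  optimum unlikely (and the 101-point audit has never caught one), not
  impossible.
* The boundary LRTs are conservative (see above); a ½χ²₀ + ½χ²₁ mixture
  reference would be less so but is deliberately not used, to match the
  field-standard tooling.
* No measurement-error model, no multi-predictor model building, no
  Ornstein–Uhlenbeck or rate-shift alternatives, no tree inference or
  dating: trees and trait tables are taken as given.
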