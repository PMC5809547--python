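# Methods

## The model

`netboot` works with Gaussian graphical models (GGMs): pairwise Markov
random fields for (latent-)normal data in which the weight of the edge
between nodes *i* and *j* is the partial correlation
ρ<sub>ij</sub> = −κ<sub>ij</sub>/√(κ<sub>ii</sub>κ<sub>jj</sub>),
with κ the precision (inverse correlation) matrix. A missing edge means
conditional independence given all remaining variables. Because a
*p*-node GGM on ordinal items carries *p* + *p*(*p*−1)/2 free parameters
(thresholds plus pairwise associations — 55 at *p* = 10, 1275 at
*p* = 50), samples typical of questionnaire research cannot support
unregularized estimation, and the package follows the standard
regularized pipeline:

1. **Input correlations** (`correlations`). Ordinal items are assumed to
   discretize a latent standard normal at per-item thresholds. Pairwise
   latent correlations are estimated by the two-step polychoric method:
   thresholds from the inverse-normal of cumulative category
   proportions, then a one-dimensional ML search for ρ on
   [−0.999, 0.999] with thresholds fixed. Mixed pairs use the analogous
   two-step polyserial; continuous pairs the product-moment correlation.
2. **Regularized GGM** (`ggm`). Graphical lasso along a log-spaced
   penalty grid of 100 values from λ_max (the largest absolute input
   correlation, where the graph is empty) down to 0.01·λ_max; the
   Extended Bayesian Information Criterion
   EBIC = −2ℓ + E·log n + 4·E·γ·log p (E = edge count, default
   γ = 0.5) picks the model. The likelihood is
   ℓ = n/2·(log det K − tr(S·K)) with constants dropped; the constant
   does not affect selection.
3. **Centrality** (`centrality`). Strength Σ|w|, closeness
   1/Σ<sub>j</sub>d(i,j), betweenness by Brandes counting with
   fractional credit for ties and endpoints excluded; shortest-path
   length of an edge is 1/|w|, which makes all indices sign-invariant
   and gives rings of constant |w| exactly equal centralities.
4. **Accuracy** (`bootstrap`, `stability`). Nonparametric bootstrap
   (rows resampled with replacement) records every edge weight and
   centrality per replicate; CIs use Hyndman–Fan type-6 quantiles
   (wider than the common type 7, which keeps bootstrap CIs from being
   anti-conservative); the bootstrapped difference test builds a CI on
   paired per-replicate differences of two statistics and flags
   significance when it excludes zero. The case-dropping (m-out-of-n)
   bootstrap re-estimates on subsets with a proportion of rows removed
   and summarizes stability as the CS-coefficient: the largest drop
   proportion at which, with 95% certainty, subset centralities still
   correlate ≥ 0.7 with the full-sample ones.

## Parameters that matter

| Parameter | Default | Notes |
|---|---|---|
| EBIC γ | 0.5 | Sparsity/sensitivity trade-off; 0 reduces to BIC. |
| λ grid | 100 values, min/max ratio 0.01 | Log-spaced; endpoints verified (empty graph at λ_max). |
| N_B (bootstrap replicates) | 1000 | The smallest usable α is 2/N_B; at N_B = 1000 that is 0.002. |
| α | 0.05 | CI level; requests below 2/N_B are refused. |
| Drop levels | 10, evenly spaced 0.1–0.75 | The 0.75 cap keeps ≥ 25% of cases; CS values are only comparable across matching grids. |
| CS threshold / certainty | 0.7 / 0.95 | Definition constants of the CS-coefficient. |
| Ordinal detection | integer-valued, ≤ 10 distinct values | Overridable per column. |

## Numerical choices

- **Bivariate normal CDF** by 16-point Gauss–Legendre quadrature of the
  single-integral (over the correlation parameter) representation;
  absolute error ~1e-8, checked against `scipy.stats.multivariate_normal`.
- **Polychoric optimization** by 40 golden-section iterations (bracket
  < 1e-8); the profile likelihood in ρ is unimodal. Contingency tables
  containing a zero cell get a 0.5 continuity constant in every cell
  (configurable off) to avoid boundary estimates at ±1. A side effect:
  two identical columns estimate slightly below the 0.999 clamp unless
  the constant is disabled.
- **Graphical lasso** by warm-started block coordinate descent (the
  standard row-wise lasso formulation), compiled with numba; the
  diagonal is not penalized. Agreement with
  `sklearn.covariance.graphical_lasso` is asserted in the test suite
  (precision entries and selected edge sets along a path). The compiled
  solver exists because the simulation studies re-estimate the network
  ~10⁵ times and need the 100-λ path in ~2 ms.
- **Edge presence** means |weight| > 1e-10 after the solve; the soft
  threshold produces exact zeros, so this is a pure numerical guard.
- **Positive-definiteness repair** clips eigenvalues at 1e-6 and
  rescales to unit diagonal, iterating because the rescaling can nudge
  the smallest eigenvalue back under the floor.
- **CI boundary**: at exactly α = 2/N_B the CI is the replicate range
  (the type-6 formula alone would interpolate just inside the extremes).
- **Zero-width difference CIs at 0** (frequent for lasso-tied edges)
  count as containing zero — not significant.
- **Failed bootstrap replicates** (e.g. a resampled column losing all
  variation) are redrawn so N_B stays as requested for the 2/N_B bound;
  more than 10% failures aborts with a diagnostic.
- **Undefined stability correlations** (zero-variance subset
  centralities) are recorded as 0 — degenerate estimates must read as
  instability, not be dropped. Constancy is detected with a 1e-10
  relative spread tolerance because shortest-path arithmetic leaves
  ~1e-16 noise on exactly-equal centralities.
- **Missing data** are handled pairwise-complete by default (listwise
  optional); the effective n attached to a correlation estimate is the
  mean pairwise-complete count.

## What the simulator emulates

`netsim` reproduces the validation designs: closed-ring "chain"
networks (each node tied to two neighbours, constant |w|, a configurable
share of negative edges), Watts–Strogatz rewiring (each edge moves one
endpoint with probability *p*<sub>r</sub>, weight and sign preserved, no
self-loops or duplicates, positive-definiteness re-verified with
redraws), multivariate-normal sampling from the implied correlation
matrix, and ordinalization at per-variable thresholds drawn i.i.d.
standard normal (redrawn until every category is observed, since
polychoric estimation needs full margins). Rewiring probability grades
the designs from "no true centrality differences" to "centralities
differ".

The synthetic 17-item fixture (`fixtures`) mimics the qualitative shape
of a symptom-scale dataset — sparse positive manifold, three dominant
edges, 4-level items, n ≈ 359 — for demos and CLI tests. It is not
derived from any real dataset, so analyses of it demonstrate the
workflow, not empirical findings. More generally the simulator draws
exactly from the model class the estimator assumes (latent normal,
monotone discretization); real data deviate (skew, local dependence,
missingness mechanisms), so passing simulations validate the machinery,
not robustness to misspecification.

## Study scales

The original studies used 1,000 replicates per condition and
N_B = 1,000 (5,000 case-drop samples over 25 levels for the CS study).
The package's desk-scale defaults, used by the validation suite and
`scripts/acceptance.py`, are chosen so each study runs in minutes on
one core: 30–100 datasets per condition, N_B = 200, 10 drop levels
(≥ 20 case-drop replicates per level, the minimum at which the
95%-certainty proportion is meaningful). Full-scale runs are a matter
of setting `SimulationDesign` fields. Monte-Carlo standard errors are
computed over replicate-level rates and reported alongside every rate.

Two findings from running these studies are worth recording:

- **Exact edge-set recovery is not a property of this estimator.** On
  ring networks at n = 2500 the EBIC-glasso selection always contains
  every true edge but typically keeps 1–5 weak spurious edges
  (|w| ≤ ~0.05); exact set equality occurs in well under half the
  seeds. This was cross-checked with an independent solver route
  (scikit-learn's graphical lasso plus the same EBIC formula) and
  matches the known behaviour of EBIC-selected glasso, whose
  specificity declines with n. Downstream conclusions are unaffected:
  the difference tests compare true-nonzero edges and remain calibrated.
- **The pooled CS-null proportion depends on the sample-size grid.**
  Under the null, subsets share most of their rows with the full
  sample, so at large n the CS-coefficient can clear 0.25 without any
  true centrality differences; pooling over {100, 500, 2500} yields a
  higher proportion of CS < 0.25 (~0.9) than pooling that includes
  still larger n. Raising case-drop replicates per level does not
  close this gap (it lowers CS further); it is a property of the
  conditions pooled, not of the replicate count.

## Limitations and extension points

- Binary (Ising) and mixed graphical models are out of scope; the
  estimator argument of the bootstrap/stability drivers accepts any
  `OrdinalDataset -> NetworkModel` callable, which is the intended
  extension point.
- No nonparanormal transformation for skewed continuous data.
- No centrality confidence intervals: bootstrap distributions of
  centrality indices are biased, which is precisely why the package
  reports stability (CS) instead of intervals.
- No Bonferroni/FDR-corrected bootstrap difference tests: a corrected
  level like 0.05/17,955 ≈ 3e-6 would need on the order of 10⁶
  replicates (α ≥ 2/N_B); the analytic count and level utilities are
  provided so users can see this for themselves.
- No p-values from bootstrap replicates, and edge CIs are never
  presented as edge-vs-zero significance tests (the lasso already
  performed selection; a retained edge is by construction "nonzero").
- Parametric bootstrap draws are continuous; with ordinal data the
  nonparametric bootstrap is the supported route (the result object
  carries a "continuous-data bootstrap" note).
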