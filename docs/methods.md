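# Methods

## Data model

Responses are an n×p matrix of integers in {0,…,3} (GAD-7: p = 7 items
A1–A7). The package's in-memory container is a plain pandas DataFrame
validated by `prep.validate_likert`; estimated networks are
`SymptomNetwork` objects (p×p symmetric weight matrix, zero diagonal,
|w| < 1, weights below 1e-10 treated as exact zeros to absorb solver
noise).

The cohort the package models was screened: only respondents with total
score ≥ 8 (the GAD-7 clinical screening threshold) enter the analysis.
The inclusion filter is therefore part of the data model, applied after
sampling in the generator and available in the pipeline
(`inclusion_min_total`, default 8; `None` disables it).

## Synthetic-data generator

Likert items are produced by discretizing a latent Gaussian vector with
per-item ascending cut points.

* **GGM truth.** `build_ggm_truth` constructs a precision matrix whose
  implied partial correlations equal a requested sparse edge set: with a
  uniform diagonal c and off-diagonals `K_ij = −w_ij·√(K_ii K_jj)`, the
  family is `K(c) = c(I − W)`, whose partial correlations equal W for
  every c. A bisection (tolerance 1e-8) finds the smallest diagonal
  making the least eigenvalue ≥ 0.05; weight patterns for which I − W is
  not positive definite are rejected with the offending magnitude named.
  The bundled reference truth uses the published GAD-7 edge weights, so
  the generator's population partial correlations reproduce them exactly.
* **DAG truth.** A linear-Gaussian structural model simulated in
  topological order; each node is standardized by its closed-form
  population SD (`Σ = (I−B)⁻¹ D (I−B)⁻ᵀ`) before discretization so one
  threshold calibration serves all nodes.
* **Thresholds.** Default cut points are calibrated so unfiltered
  marginal means match the published cohort descriptives (≈1.3–1.9 per
  item): the target level distribution is a normal with the item's
  published mean and SD binned at half-integer boundaries, mapped to
  standard-normal quantiles. The published means describe the
  *post-filter* cohort while the calibration is applied to the
  *pre-filter* latent population — an approximation, since the source
  population is not characterized; with the filter on, simulated
  marginals sit slightly above the published values.
* **What the generator does not emulate:** item-specific response styles,
  local dependence beyond the Gaussian copula, measurement
  non-invariance, and missingness (the modeled survey allowed only
  complete submissions). Passing recovery tests on these data certify
  the estimators under a correctly specified latent-Gaussian ordinal
  model, not robustness to those real-data features.

## Network estimation

Pipeline: nonparanormal transform → Spearman matrix → positive-definite
repair → graphical-lasso path → EBIC selection → partial correlations.

* **Nonparanormal transform.** Shrunken-ECDF variant with midranks:
  u = rank/(n+1), z = Φ⁻¹(u), rescaled to unit sample SD (a
  truncated-ECDF variant is available). The transform is rank-preserving,
  so the Spearman matrix is exactly invariant — the bootstrap/permutation
  fast path exploits this identity by correlating midranks directly.
* **Positive-definite repair.** Eigenvalues clipped at 1e-8,
  reconstruction rescaled to unit diagonal; the repair flag and Frobenius
  change are reported. The operation is idempotent.
* **Graphical lasso.** Block coordinate descent with the ℓ1 penalty on
  off-diagonals only (working-covariance diagonal pinned to the sample
  variances), solved along a descending log-spaced grid of 100 λ values
  from λ_max (the smallest λ giving an empty graph) down to 0.01·λ_max,
  warm-starting each level. λ = 0 falls back to direct inversion. The
  solver is verified against scikit-learn's graphical lasso in the test
  suite.
* **EBIC selection.** `EBIC = −2ℓ + E log n + 4γE log p`, γ = 0.5 by
  default, ties toward the sparser (larger-λ) model. By default ℓ is the
  log-likelihood of the *support-restricted unpenalized MLE* of each
  candidate sparsity pattern (computed by a restricted block solver), and
  the reported weights are that refit's partial correlations. Rationale:
  evaluating EBIC at the penalized estimate makes the criterion monotone
  in λ whenever the true graph is dense — shrinkage bias on strong edges
  dominates the edge penalty, so the densest model always wins — whereas
  the refit form scores the sparsity pattern itself. The penalized
  variant (likelihood evaluated at, and weights reported from, the
  glasso estimate) remains available via `likelihood="penalized"`.
* **Operating characteristics.** At n = 2000 the refit-EBIC detection
  threshold for a single partial correlation is ≈ `√((log n + 4γ log p)/n)`
  ≈ 0.076. Against the reference truth (six of whose eighteen edges lie
  at 0.03–0.07) this yields support sensitivity ≈ 0.77 with
  false-positive rate ≈ 0.03; the weak edges are below any BIC-type
  detection limit at this sample size. Null data (empty truth) yield an
  empty network in ≥ 95% of runs.

Expected influence is the exact signed row sum of the weight matrix.
Predictability regresses each transformed node on all other nodes
(OLS R²; an upper bound, since edge directions are unknown); a flag
restricts predictors to estimated neighbors.

## Stability and difference tests

The edge bootstrap resamples rows with replacement and reruns the entire
estimation pipeline per replicate (B = 2000 by default; desk-scale runs
use less); 95% CIs are percentile intervals. Difference tests reuse the
same ensemble (a single ensemble serves accuracy and difference testing):
two edges or two nodes differ significantly when the percentile CI of the
bootstrapped difference excludes zero (α = 0.05, uncorrected). The CS
coefficient uses drop proportions {0.05, …, 0.75}; for each proportion B
subsamples are drawn without replacement and the CS value is the largest
proportion at which ≥ 95% of subsample EI vectors correlate ≥ 0.7 with
the full-sample EI (0 if none qualifies). Because each bootstrap
replicate repeats support selection, edge replicate distributions are
mixtures with an atom at zero; percentile CIs may exclude the replicate
mean, which is expected behaviour.

## Community detection

igraph's spinglass (spins = p, resolution 1, start/stop temperatures and
cooling at igraph defaults) and walktrap (4-step walks, dendrogram cut at
maximum modularity). Both require non-negative weights and a connected
graph; signed variants are out of scope since estimated anxiety networks
here are all-positive. Spinglass is annealing-based, so the partition
returned is the best of 20 seeded restarts by weighted modularity — at
p = 7 this is verified against exhaustive enumeration of all 877 set
partitions in the tests, making the result effectively deterministic.

On the bundled *rounded* reference matrix, walktrap assigns A4 to the
cognitive cluster ({A1,A2,A3,A4}/{A5,A6,A7}): A4's summed weight toward
A1–A3 (0.33) exceeds its somatic side (0.30) after rounding to two
decimals. Spinglass returns the modularity-optimal
{A1,A2,A3}/{A4,A5,A6,A7}. The same walktrap behaviour is reproduced by
the R igraph implementation, so this is a property of the rounded input,
not of the port.

## Two-group comparison

Observed networks for both groups are estimated with identical pipeline
settings; S = |difference in global strength|, M = maximum absolute
edge difference, plus per-edge and per-node-EI absolute differences.
Group labels are permuted (group sizes preserved) and both networks
re-estimated per iteration; p-values use the add-one rule
`(1 + #{null ≥ obs})/(1 + B)` and are therefore never exactly zero. Edge
p-values are uncorrected (no a-priori hypotheses); EI p-values are
reported both raw and Holm-adjusted. The pooled rows are canonically
sorted before the seeded permutation stream is drawn, which together with
the absolute-difference statistics makes the result invariant to swapping
the two groups.

## DAG structure learning

Score: decomposable Gaussian BIC, `Σ_i [ℓ_i(parents) − (k_i/2) log n]`
with `k_i = |parents| + 2` (intercept and residual variance), computed
from sufficient statistics (the MLE covariance) with per-family caching.
Raw 0–3 scores are passed as continuous variables, the convention of
Gaussian-score learners applied to questionnaire items; the nonparanormal
matrix can be supplied instead. Greedy hill-climbing applies the best
single acyclicity-preserving arc addition/deletion/reversal until no move
gains more than 1e-9; each of `restarts` (default 50) escape attempts
perturbs the incumbent with `perturbations` (default 100) random legal
changes and re-climbs, keeping the best score.

Bootstrap model averaging learns a DAG per row-resample (B = 10,000 at
full scale; bootstrap climbs default to a 5×50 schedule for tractability,
both configurable). The retention cutoff minimizes the L1 distance on
[0, 1] between the ECDF of pair frequencies and the ideal CDF of a
perfectly separated ensemble (a fraction ℓ of pairs at frequency 0, the
rest at 1), taking the ℓ̂-quantile of the observed frequencies and
keeping pairs strictly above it; ties favour the larger level (higher
specificity). Kept pairs are oriented by bootstrap majority; a majority
below 51% (including exact ties, oriented toward the lower-indexed node)
keeps the arc but flags it direction-uncertain — mirroring the
convention of drawing such arcs dotted rather than dropping them. If
majority orientation creates a cycle, the lowest-frequency arc in each
cycle is deleted until a topological order exists. Final strengths are
ΔBIC on deletion refit against the full data; supportive arcs are
negative.

## Numerical and design choices

* Coordinate-descent tolerances: 1e-6 on the working covariance
  (relative to the off-diagonal scale), inner lasso at a tenth of that;
  restricted-MLE refits at 1e-9. The path solver and refits are
  numba-compiled; first call pays a few seconds of JIT compilation
  (`glasso.warmup()`).
* Problem sizes in the shipped analyses and tests are desk-scale by
  design: simulated cohorts of 1–5k rows, bootstraps of 100–500,
  permutation tests of 100–250 iterations, DAG averaging at B = 200 with
  a 5×50 schedule. All counts scale up through function arguments.
* All randomized stages take explicit integer seeds; the pipeline driver
  derives stage seeds from one root seed via `SeedSequence.spawn`.
* Seeded runs are bit-reproducible (bootstraps, permutations, spinglass
  restarts, layouts).

## Known limitations

* Weak edges (|partial correlation| below ≈ √(log n/n)) are invisible to
  any BIC-type selector; reported networks at questionnaire-study sample
  sizes are conservative about faint connections.
* The Gaussian DAG score applied to 4-level ordinal items inherits
  discretization distortion: conditional independences of the latent
  model do not hold exactly for the discretized scores, which inflates
  the bootstrap frequency of spurious pairs relative to continuous data.
* Predictability and reliability computed on a screened (total ≥ 8)
  cohort are attenuated by selection — the generator reproduces this
  (its screened cohorts show visibly lower Cronbach's α and nodewise R²
  than unfiltered draws), and no correction is attempted.
* Community detection requires non-negative weights; signed spinglass is
  not implemented.
* The DAG framework excludes feedback loops by construction; arcs are
  probabilistic-priority statements, not causal effects.
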