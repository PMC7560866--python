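# Methods

## Model and procedure

`priorcut` treats network inference as a one-parameter model selection
problem. The data are an N × k matrix of preprocessed, approximately
Gaussian abundances; the candidate family is the set of graphs
G(t) = {(i, j) : |r_ij| ≥ t} obtained by thresholding a correlation
matrix at t ∈ [0, 1] (inclusive rule, so the network at the statistical
cutoff equals the significant set; ties at the cutoff are all included).
The selection criterion is agreement with a biological reference network:
each unordered pair of evaluated variables is classified as TP/FP/FN/TN by
crossing (|r_ij| ≥ t) with (edge in reference), and the candidate is scored
by the two-sided Fisher's exact test on that 2×2 table. The optimal cutoff
maximizes the mean −log10 p across bootstrap resamples.

Assumptions worth stating explicitly:

* The reference needs to contain *some* truth, not *all* truth — the
  optimum is empirically stable under substantial edge removal, rewiring
  and coarsening (this is the package's central, tested property), but a
  fully random reference carries no signal and triggers a warning ("no
  cutoff beats the empty network") rather than a misleading optimum.
* Two-sidedness means strong *depletion* of reference edges also yields a
  small p. The odds ratio (TP·TN)/(FP·FN) is reported alongside the score
  so depletion-driven optima can be recognized; it never alters the score.
* F1 and Matthews correlation are available as diagnostics on
  `OverlapTable` but are never the selection criterion (F1 ignores true
  negatives, which dominate sparse biological networks).

## Correlation estimators

* **pearson** — `np.corrcoef`; two-sided p from t = r·√((N−2)/(1−r²)) on
  N−2 degrees of freedom.
* **parcor** — exact partial correlation: invert the covariance matrix Σ,
  pcor_ij = −Ω_ij/√(Ω_ii Ω_jj). Requires N > k; the error message points
  to the shrinkage estimator otherwise. p-values use the same t-form with
  N−2−(k−2) degrees of freedom (one lost per conditioned variable).
* **shrinkage** — partial correlation from R\* = (1−λ\*)R + λ\*I with the
  analytic intensity λ\* = Σ_{i<j} V̂ar(r_ij) / Σ_{i<j} r_ij², clamped to
  [0, 1]; V̂ar(r_ij) uses the standard unbiased w-statistics formula
  n/(n−1)³ · Σ_k (w_kij − w̄_ij)² with w_kij the products of standardized
  observations. The shrinkage target is the identity correlation matrix
  with unshrunk unit variances. Works for N < k by construction.

### Empirical null for shrinkage p-values

Shrunk partial correlations no longer follow the classical t law, so the
null density f₀(r; κ) ∝ (1−r²)^((κ−3)/2) is fitted to the observed
coefficients. Because some coefficients are genuinely non-null, κ is
estimated by **truncated maximum likelihood**: only coefficients with |r|
at or below the 90th percentile of the observed |r| distribution enter, and
the likelihood is that of the null density *conditioned on the truncation
window* (normalized by P(|r| ≤ c; κ) via the regularized incomplete beta
function). The conditioning matters: a plain MLE on a truncated sample is
biased toward small κ and would not recover the truth even on pure null
data. Optimization is bounded scalar minimization over log(κ−1), with an
error raised if the optimum pins to the κ → 1 boundary. Two-sided p-values
are p(r) = 1 − I_{r²}(1/2, (κ−1)/2), computed through the mirrored
incomplete beta I_{1−r²}((κ−1)/2, 1/2) for accuracy at large |r|; they are
monotone decreasing in |r| for a fixed κ, so edge ranking is preserved.
The null proportion is summarized as η₀ = clamp(2 · fraction(p > 0.5), 0, 1).
This scheme is a deliberately simple stand-in for full mixture-density
machinery; it is validated by parameter recovery (κ = 100 recovered within
~6% median from 1225 null coefficients) and bit-compatibility with other
implementations is not a goal. A degenerate all-null case (every
coefficient exactly 0, e.g. λ\* = 1) short-circuits to p ≡ 1.

## Fisher overlap score

The hypergeometric point probability of the observed table is the kernel;
the two-sided p sums the point probabilities of all tables with the same
margins whose PMF is ≤ the observed PMF, with a relative tolerance of 1e-7
on the comparison to absorb floating-point ties. All terms are computed in
log space (gammaln), so pair counts up to ~1e8 (transcriptome-scale
pathways) neither overflow nor underflow; optimization curves use the log-p
directly, so −log10 p is exact even when p underflows a double. Any zero
margin returns p = 1 exactly. The implementation is verified against
exhaustive exact-integer enumeration for every table with total ≤ 40
(135,751 tables, max |Δp| ≈ 5e-14) and spot-checked against an independent
library implementation.

Multiple-testing adjustment (BH step-up, Bonferroni) delegates to
statsmodels and is cross-checked against a hand-coded oracle. The
**statistical cutoff** at level α is the smallest |r| among pairs with
adjusted p ≤ α, always computed on the full correlation matrix (not the
reference-restricted one); when nothing is significant a sentinel above 1
is returned, meaning "empty network".

## Optimization protocol

* Bootstrap = resampling N rows **with** replacement; subsampling (for
  sample-size profiles) = **without** replacement. Replicate b of a run
  with master seed s uses `numpy.random.default_rng(s + b)`, so external
  reimplementations can match runs exactly.
* The correlation matrix (including λ\* and κ) is re-estimated once per
  replicate and thresholded at every grid cutoff — one fit, many
  thresholds. Re-fitting the null per replicate is the self-consistent
  choice; reusing full-data fits would leak information across replicates.
* Default grid: 0.00–1.00 in steps of 0.01. Bands are 2.5/97.5 percentile
  across replicates.
* Ties at the maximum break toward the **largest** cutoff (sparsest
  network) — conservative edge inclusion.
* Variables absent from the reference node set (or from an explicit
  evaluation mask, e.g. unidentified metabolites) are kept for estimation
  but excluded from overlap scoring.
* Reporting and validation evaluate the *original* (un-resampled) data
  network at the bootstrap-selected cutoff, including against a second,
  disjoint reference built with `prior_difference`.

## Reference degradation

* `subsample_prior` keeps round(f·E) edges uniformly (round half away from
  zero, for platform-stable counts); nodes isolated by removal stay in the
  node set, so the evaluated pair universe is unchanged — the alternative
  (dropping them) would silently shrink the TN pool.
* `rewire_prior` performs accepted degree-preserving double-edge swaps
  ((a,b),(c,d) → (a,d),(c,b)); rejected swaps (self-loop/duplicate) do not
  consume the budget. A `uniform` mode (delete an edge, add a random
  non-edge) exists for sensitivity checks but does not preserve degrees.
* `randomize_prior` places the same edge count uniformly among all C(n,2)
  pairs — simpler than exhaustive rewiring and matching "fully random" in
  distribution of overlap (expected overlap with the original E²/C(n,2)).
* `block_prior` builds the coarse class-based reference (cliques within
  each class); `intersect_priors`/`prior_difference` combine references,
  treating nodes missing from one side as isolated.

## Preprocessing chain

Applied in fixed order: PQN (raw scale) → log transform → missingness
filter → KNN imputation → covariate residualization.

* **PQN**: reference spectrum = per-variable median over all samples (or a
  user-supplied fixed reference); per-sample dilution factor = median of
  quotients against the reference; rows divided by their factor. For a
  fixed reference the dilution factor cancels any per-sample scale factor
  *exactly*; with the self-derived reference, rescaling samples also moves
  the medians, so exact invariance holds only when the scaled samples do
  not set any per-variable median. Strictly positive input is required.
* **Missingness filter**: variables with more than 20% missing are dropped
  first, then samples with more than 10% — strictly-greater thresholds, in
  that fixed order (a sample can survive solely because a bad variable was
  removed first).
* **KNN imputation** (default k = 10): neighbours are the k variables most
  correlated (absolute pairwise-complete Pearson) with the target that are
  observed in the affected sample; each contributes a univariate regression
  prediction with moments taken over the jointly observed samples, averaged
  with weights |r|. This makes a perfectly correlated neighbour reproduce
  its value exactly and respects anticorrelated neighbours' signs. It is a
  correlation-ranked variant of KNN imputation, not a reimplementation of
  any specific published pre-selection scheme; imputation here is plumbing,
  not the inferential target.
* **Residualization**: OLS residuals on intercept + covariates, samples
  aligned by ID (inner join, drops logged). Categorical covariates are
  one-hot encoded dropping the first level; constant columns duplicate the
  intercept and are dropped; a rank-deficient design raises an error naming
  the collinear columns. The operation is idempotent.

## Synthetic data generator

`random_pathway` builds a seeded graph with an exact edge count
(`chain_lattice`: backbone path plus second-neighbour rungs, mimicking a
sparse low-degree synthesis pathway; also Erdős–Rényi and scale-free).
`ggm_from_graph` places −strength (random sign) at each edge of a
unit-diagonal precision matrix; if not positive definite the diagonal is
inflated by |λ_min| + 0.05 and re-normalized to unit partial variances.
Diagonal inflation is deterministic and always terminates, at the price of
shrinking achieved edge strengths below nominal — the achieved values are
recorded and tests use them, not the nominal number. Non-edge partial
correlations are exactly zero by construction. `sample_data` draws
multivariate normal samples (Cholesky), optionally adds linear effects of
an age-like continuous and a gender-like binary covariate, and punches
missing cells completely at random.

What the generator emulates: preprocessed, covariate-affected, Gaussian-ish
omics matrices with a sparse known interaction structure. What it does not:
raw-scale artefacts (counts, heteroscedastic MS noise, batch/run-day
structure, compositional constraints, informative missingness). Passing
tests therefore demonstrate correctness of the estimators and of the
selection machinery under the stated model, not robustness to every
real-data pathology upstream of the pipeline.

## Study conditions used by the tests and acceptance script

The standing fixture is a 50-node / 60-edge chain-lattice pathway GGM with
nominal edge |pcor| 0.25 and N = 600 samples — sized like a
well-characterized glycomics panel measured in a mid-sized cohort, where
the shrinkage estimator is comfortably identified yet bootstrap noise is
visible. Robustness and recovery checks use 100 bootstrap replicates, 20
repetition seeds, the 0.01-step grid, 50%-edge subpriors and 20%-edge
rewiring (6 double-edge swaps); sample-size profiles use N ∈ {100, 200,
400} with one subsample per seed. These are the package's reference
conditions; all of them are plain function arguments.

## Known limitations

* The empirical-null fit assumes the bulk of coefficients is null; with
  very dense true graphs (>~30% of pairs) the truncation heuristic will
  absorb signal into κ and p-values become conservative.
* `parcor` is undefined for N ≤ k and unstable for N ≈ k; the sample-size
  profile emits missing rows there rather than guessing.
* The Fisher score compares unweighted, undirected graphs; edge weights,
  directions and signs in the reference are ignored.
* MCAR missingness only in the generator; the imputer is exercised, not
  stress-tested against informative missingness.
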