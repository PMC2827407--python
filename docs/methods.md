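# Methods

## The benchmark model

`mvbench` treats imputation quality as a two-stage question. Stage one
is numeric: from a complete reference matrix X (G genes × n
conditions, log₂ ratios), a mask M of entries is erased at rate τ
(percent of eligible entries, drawn uniformly without replacement,
genes free to lose several or all values), each method produces
estimates x̂ᵢⱼ for (i,j) ∈ M, and accuracy is RMSE over M (unnormalised,
on the log₂ scale; a variant divided by the truth standard deviation is
available behind a flag). Stage two is structural: clusterings of the
completed matrix (GC) are compared to clusterings of the reference
matrix (RC) with CPP, CPP_f and CAR. All methods of a design cell
impute the *identical* mask, so pairwise win rates are paired
comparisons.

Eligible entries are either all G·n cells or the extreme subset: the
round(f·G·n) entries with largest |value| (default f = 1 %, ties at the
cutoff broken by (gene, condition) order). Masking τ = 10 % of the 1 %
extreme set therefore touches 0.1 % of the matrix.

Counts follow round-half-away-from-zero; the rate grid 0.5–50 % in
steps of 0.5 % with 100 replicates is the canonical sweep. Randomness
is counter-based: a master seed spawns one independent substream per
(dataset, scope, τ, replicate) cell, so any single replicate is
reproducible in isolation.

## The distance and the stability indices

Profiles with gaps are compared with the masked normalized Euclidean
distance d* = √( n/(n−m) · Σ_obs (vᵢ−wᵢ)² ), m being the number of
coordinates missing in either profile. d* reduces to the plain
Euclidean distance on complete profiles. Pairs with no shared observed
coordinate are undefined; the all-pairs matrix substitutes the largest
finite distance and counts the substitutions rather than inventing
similarity.

Agreement indices for partitions of the same genes:

* **CPP** = 100/G · Σ over RC clusters of the largest overlap with any
  GC cluster. Normalisation by G (not by cluster count) makes CPP the
  fraction of genes that stayed with their cluster's best match.
* **CPP_f** relaxes the best match to the union of the matched GC
  cluster and the f−1 GC clusters whose centroids (mean profiles in the
  completed matrix) lie nearest to it; f = 1 reduces exactly to CPP and
  f ≥ K saturates at 100.
* **CAR** is the Rand index × 100, computed by pair counting on the
  K_RC × K_GC contingency table (O(G + K²)) and cross-checked in the
  tests against O(G²) enumeration and an independent library
  implementation.

Hierarchical clustering uses the Lance–Williams recurrences (scipy)
for single, complete, average, McQuitty (= "weighted"), median,
centroid and Ward linkages on the d* matrix, cut to K clusters;
k-means runs on the completed matrix with seeded restarts. The cluster
count K is a configuration parameter (default 10); the
within-cluster-dispersion report (mean over clusters of the average
squared distance to the centroid) lets users match comparable K across
algorithms, since k-means and the linkages produce clusters of very
different compactness.

## The imputers

All ten methods share one contract: observed entries pass through
bit-for-bit, every masked entry receives a finite estimate, and any
entry a method cannot estimate falls through the chain *gene observed
mean → condition observed mean → global observed mean → 0*, with the
usage counted in `params["fallbacks"]`. All methods are deterministic
given the data and hyperparameters (internal cross-validation derives
its stream from the dataset's seed).

* **row_mean** — the gene's observed mean.
* **knn** (k = 10 default) — donors are genes observed at the target
  condition sharing ≥ 1 observed coordinate; distance d*; estimate is
  the 1/(d*+ε)-weighted mean of the k nearest donors' values (ε = 1e−9,
  so an exact duplicate dominates). `select_k_opt` picks k from a
  candidate list by secondarily masking 5 % of the *observed* entries
  and minimising RMSE on them (ties → smallest k).
* **sknn** — genes sorted by ascending missing count; complete genes
  seed the donor pool; each imputed gene joins the pool and can donate
  to later genes. With no complete gene, the least-missing gene is
  seeded by its row mean (recorded).
* **llsi** (k = 10 or `"auto"` over {5,10,15,20}) — the target gene's
  observed part w is approximated as a least-squares combination of
  its k nearest complete neighbours (pseudoinverse), and the
  combination is extrapolated to the missing coordinates.
* **lsi_gene** (K = 10) — per masked entry, the K neighbours with
  largest |Pearson r| (≥ 3 mutually observed coordinates; constant
  neighbours disqualified) each contribute their simple-regression
  prediction, blended with weights (r²/(1−r²+1e−6))², which diverge as
  |r| → 1.
* **lsi_array** — single pass: mean vector μ and condition covariance
  Σ from the complete genes only (ridge 1e−8), then the
  multivariate-normal conditional expectation
  μ_M + Σ_MO Σ_OO⁻¹ (x_O − μ_O) per incomplete gene.
* **em_array** — classical EM for an n-variate normal with genes as
  observations: missing cells initialised by row means; E-step fills
  conditional expectations and accumulates conditional covariances;
  M-step re-estimates (μ, Σ) with the correction; iterate until the
  max relative change in (μ, Σ) drops below 1e−6 (max 300 iterations;
  non-convergence is a flag, not an error). The observed-data
  log-likelihood trace is recorded and is non-decreasing — asserted in
  the tests. Requires n ≤ 64.
* **em_gene** (K = 10) — the same EM machinery per incomplete gene on
  the small system of the gene plus its K most |r|-correlated
  neighbours, with variables = genes and observations = conditions and
  ridge 1e−6 (the n-observations-for-(K+1)-variables covariance is
  rank-deficient). Default tolerance 1e−4 / 100 iterations: under rank
  deficiency the ridge-regularised covariance drifts slowly and a 1e−6
  relative criterion is rarely reachable, while the estimates are
  stable after ~10 iterations.
* **lsi_combined** — p·(gene estimate) + (1−p)·(array estimate);
  p ∈ [0,1] fixed or `"auto"`: grid {0, 0.01, …, 1} minimising RMSE on
  a 5 % secondary mask of observed entries. p = 1/0 reduce exactly to
  lsi_gene/lsi_array.
* **lsi_adaptive** — as lsi_combined but p varies per entry with
  r_max (the strongest gene-space correlation available to that
  entry), in 10 equal-width bins on [0,1]; bins with < 20 secondary
  entries inherit the global p.
* **bpca** — reserved name; an external algorithm exposed only as a
  plugin hook (`register_method("bpca")`).

The LSI/EM internals (neighbour counts, weight formula, binning,
secondary-masking estimation of k and p, EM initialisation, ridge
magnitudes, tolerances) are this package's own concrete definitions;
they are recorded per run in `ImputationResult.params` for audit.

## The synthetic generator

`generate_dataset(SyntheticSpec(...))` emulates a refined microarray
compendium. Defaults — G = 500 genes, n = 8 conditions, C = 10
clusters, centroid spread σ_between = 1.0 and within-cluster noise
σ_within = 0.25 (log₂ units), 10 % flat genes, non-kinetic — are shaped
on a small non-kinetic yeast subset (~800 genes × 8 conditions).
Non-kinetic centroids are drawn i.i.d. per condition from
N(0, σ_between²); kinetic centroids are sinusoids
a·sin(2πt/n + φ) + b with a ~ U(0.5σ_b, 2σ_b), φ ~ U(0, 2π),
b ~ U(−σ_b, σ_b) per cluster — a one-parameter-family smoothness that
gives conditions the serial correlation typical of time courses. Genes
are centroid + N(0, σ_within²) noise; flat genes are pure noise around
zero with a dedicated label (real analyses that skip profile filtering
retain such genes, and they flatter mean-reverting imputers' apparent
cluster stability). Every cluster is guaranteed at least one member;
gene order is randomly permuted.

**What passing tests on this generator do and do not show.** The
generator produces well-separated point-mass clusters plus isotropic
noise. That is enough to test every contract exactly, to demonstrate
cluster-stability degradation with τ, and to separate structure-using
methods from `row_mean` (which cannot beat the centroid spread). It is
*not* a faithful model of real expression data in one important
respect: its clusters are so clean that kNN finds near-perfect donors
and attains its theoretical floor σ_within·√(1+1/k), below the best
*linear* predictor's floor — so the real-data finding that the
array-space EM dominates kNN does **not** reproduce here, and the
package does not claim it does. On genuinely multivariate-normal data
(factor structure + noise) `em_array` matches the closed-form
conditional expectation to three decimals and beats kNN decisively;
both regimes are covered in the tests. Conclusions about which method
wins on a real dataset should come from running the benchmark on that
dataset.

## Numerical choices and degenerate inputs

* Missing tokens accepted on input: "", "NA", "nan", "NaN"; always
  written as "NA". Values are written with 17 significant digits
  (round trips are lossless to ≥ 12).
* The condition-drop threshold of the reference-matrix filter is an
  absolute MV count, disabled by default (the historical cutoff of 80
  was dataset-specific). Gene order is never re-sorted, keeping seeded
  subsampling reproducible.
* No guard prevents a gene from losing all its values at high τ;
  robustness is the fallback chain's job, and fallback usage is
  reported rather than hidden.
* Covariance solves prefer Cholesky (`assume_a="pos"`) and degrade to
  least squares on numerical failure; tiny ridges (1e−8 array-space,
  1e−6 gene-space) keep exactly collinear conditions invertible while
  perturbing recovered values by ≪ 1e−5.
* Win-rate ties contribute 0.5 to each side, so cell(A,B)+cell(B,A) =
  100 exactly.
* fcluster can merge ties into fewer than K clusters; labels are
  compacted and the realised K is reported.

## Problem sizes used in the checked results

The shipped tests and the acceptance script run the full pipeline at
G = 500 × n = 8 with 30 replicates for the ranking and stability
checks, 20 seeded fixtures for EM monotonicity, and G = 200 for the
pair-enumeration cross-checks — sizes chosen so the whole suite
completes in well under a minute per check while leaving the test
statistics (paired sign tests at α = 0.01) fully powered. The
full-scale sweep (100 τ levels × 100 replicates × several datasets)
is available through `BenchmarkConfig`/`run_benchmark`, which writes
records incrementally and supports resuming.

## Known limitations

* BPCA is a hook, not an implementation; comparisons involving it
  require a user-supplied plugin.
* CPP_f's "nearby clusters" are defined by centroid proximity in
  expression space; other operationalisations (tree distance, shared
  boundary) would give different absolute values.
* The generator does not model spot-level noise, dye bias,
  missing-not-at-random mechanisms, or empirical value distributions
  of specific compendia.
* Clustering on matrices that still contain MVs (via d*) is supported,
  but the stability pipeline scores completed matrices; mixed-mode
  comparisons are left to the user.
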