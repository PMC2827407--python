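# mvbench

Benchmarking framework for **missing-value (MV) imputation in
gene-expression matrices**, and for the question practitioners actually
care about: *after the holes are filled in, are the gene clusters still
the same?*

Microarray (and other expression) pipelines filter corrupted spots, so
the genes × conditions matrix of log₂ ratios arrives with missing
cells. Analysts either drop affected genes, substitute zeros, or impute.
`mvbench` quantifies the third option end to end with the classic
simulate-mask → impute → score → cluster → score design:

1. build a complete **reference matrix** (drop conditions with too many
   MVs, then every gene with any MV);
2. erase a controlled fraction **τ** of entries (τ = 0.5–50 %, drawn
   uniformly; optionally restricted to the 1 % of entries with the
   largest |log₂ ratio| — the *extreme values*, biologically the most
   interesting and hardest to impute);
3. impute with any of ten methods behind one interface:
   `row_mean`, `knn`, `sknn`, `llsi`, `lsi_gene`, `lsi_array`,
   `lsi_combined`, `lsi_adaptive`, `em_gene`, `em_array`
   (plus a `bpca` plugin hook);
4. score the estimates x̂ against the held-out truth x by
   **RMSE** = √(1/|mask| Σ (x̂ − x)²) and the Pearson correlation R;
5. re-cluster the completed matrix (seven hierarchical linkages via the
   masked distance d*, plus k-means) and compare the generated
   clustering (GC) to the reference clustering (RC) with
   **CPP** (per-RC-cluster best-match overlap, % of genes),
   **CPP_f** (ditto, relaxed to the f = 5 nearest generated clusters) and
   **CAR** (% of gene pairs co-clustered in both or separated in both —
   the Rand index × 100).

The masked profile distance is

    d*(v, w) = sqrt( n/(n−m) · Σ_observed (v_i − w_i)² )

where m counts coordinates missing in v and/or w, so incomplete
profiles remain comparable to complete ones.

A seeded synthetic-data generator (`SyntheticSpec` / `generate_dataset`)
emulates the structure of refined microarray compendia — G genes ×
n ≈ 6–16 conditions, C co-expression clusters, optional kinetic
(smooth temporal) centroids, a fraction of near-flat "null" genes —
so every stage is testable without downloads. Real data are read from
tab-delimited text (plain or Stanford PCL dialect, `NA`/empty = missing).

## Worked example

```python
from mvbench import (MethodSpec, SyntheticSpec, generate_dataset,
                     impute, rmse, simulate_mask)

matrix, labels = generate_dataset(SyntheticSpec(seed=0))   # 500 x 8, 10 clusters
data = simulate_mask(matrix, tau=10.0, seed=1)             # hides 400 entries
for name in ("row_mean", "knn", "em_array"):
    result = impute(MethodSpec(name), data)
    print(name, round(rmse(result, data), 4))
```

prints

```
row_mean 0.9753
knn 0.2779
em_array 0.6092
```

i.e. on this synthetic dataset a gene's own mean misses by ~1 log₂
unit, the multivariate-normal conditional expectation (`em_array`)
roughly halves that by exploiting cross-condition covariance, and kNN
gets within ~0.28 of the truth because the generator's co-expression
clusters hand it near-perfect donor genes. `examples/` contains one
short script per capability (generation + masking, paired method
comparison, cluster-stability curves, a full benchmark sweep with
mean-RMSE / win-matrix / stability summaries), and the `mvbench` CLI
exposes the same verbs (`generate`, `mask`, `impute`, `cluster`,
`benchmark`, `summarize`) for shell use.

Cluster stability from `examples/cluster_stability.py` (Ward, K = 10,
kNN imputation): even modest missing rates start to erode the clusters,
and by τ = 50 % a third of the genes have left their best-matching
cluster while CPP_f and CAR stay high — strayed genes mostly land in
neighbouring clusters:

```
 tau %     CPP   CPP_f     CAR
   0.5  100.00  100.00  100.00
  10.0   99.80  100.00   99.93
  20.0   99.00   99.80   99.62
  50.0   67.40   94.40   88.75
```

## Scope notes

Inputs are assumed to be pre-processed log-ratios; normalization,
SMD/GEO retrieval and BPCA itself (hook only) are out of scope. See
`docs/methods.md` for the model assumptions, parameter defaults and
known limitations — including which conclusions about real data the
synthetic benchmark can and cannot support.
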