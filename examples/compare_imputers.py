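"""Impute one simulated mask with every method and score the estimates.

All methods see the identical mask, so their RMSEs are directly
comparable (this pairing is what the benchmark's win matrices rely on).
Lower RMSE = estimates closer to the held-out true values; r is the
correlation between estimates and truths.
"""

from mvbench import (
    MethodSpec,
    SyntheticSpec,
    generate_dataset,
    impute,
    predicted_true_correlation,
    rmse,
    simulate_mask,
)

matrix, _ = generate_dataset(SyntheticSpec(seed=0))
data = simulate_mask(matrix, tau=10.0, seed=1)
print(f"imputing {data.n_masked} masked entries (tau=10%)\n")
print(f"{'method':14s} {'rmse':>8s} {'r':>7s} {'fallbacks':>9s}")
for name in ("row_mean", "knn", "sknn", "llsi", "lsi_gene", "lsi_array",
             "lsi_combined", "lsi_adaptive", "em_gene", "em_array"):
    result = impute(MethodSpec(name), data)
    r = predicted_true_correlation(result, data)
    print(f"{name:14s} {rmse(result, data):8.4f} "
          f"{(r if r is not None else float('nan')):7.3f} "
          f"{result.params['n_fallback']:9d}")
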