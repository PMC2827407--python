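"""Generate a synthetic clustered expression matrix and simulate missing values.

Builds a 500-gene x 8-condition matrix with 10 co-expression clusters
and 10% flat genes, then hides 10% of the entries (and, separately,
10% of the 1% most extreme entries) the way a benchmark replicate does.
"""

from mvbench import (
    SyntheticSpec,
    extreme_value_set,
    generate_dataset,
    simulate_extreme_mask,
    simulate_mask,
)

spec = SyntheticSpec(seed=0)
matrix, labels = generate_dataset(spec)
print(f"matrix: {matrix.n_genes} genes x {matrix.n_conditions} conditions, "
      f"{labels.K} ground-truth classes (incl. flat)")

data = simulate_mask(matrix, tau=10.0, seed=1)
print(f"tau=10% masks {data.n_masked} of {matrix.values.size} entries")

extreme = extreme_value_set(matrix, fraction=0.01)
xdata = simulate_extreme_mask(matrix, tau=10.0, fraction=0.01, seed=1)
print(f"extreme set: {len(extreme)} entries (1% with largest |log2 ratio|); "
      f"tau=10% of it masks {xdata.n_masked} entries "
      f"= {100 * xdata.n_masked / matrix.values.size:.1f}% of the matrix")
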