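# blocknmtf

Block-wise non-negative matrix tri-factorization (NMTF) for co-clustering
large non-negative data matrices — gene expression, DNA methylation,
interaction networks, or any instances-by-features table.

NMTF decomposes a non-negative matrix **X** (n × m) into three
non-negative factors

    X ≈ U S Vᵀ,   U ∈ ℝ₊^{n×k1},  S ∈ ℝ₊^{k1×k2},  V ∈ ℝ₊^{m×k2}

by minimising the squared Frobenius reconstruction error
F(U,S,V) = ‖X − U S Vᵀ‖²_Fro with multiplicative update rules.  Unlike
two-factor NMF, the middle factor **S** maps interactions between a row
latent space and a separate column latent space, which suits non-square
data: rows of **U** assign instances to row clusters, rows of **V**
assign features to column clusters, and S[a, b] scores how strongly row
cluster *a* interacts with column cluster *b*.  An orthogonal variant
(UᵀU = I, VᵀV = I) sharpens this co-cluster reading.

The point of this package is *scaling by blocks*: **X** is partitioned
into an N × M grid (equal-size blocks for dense matrices, blocks holding
approximately equal numbers of nonzeros for sparse ones), **U** is
row-partitioned, **V** column-partitioned, and **S** replicated.  The
update rules are rewritten so each band needs only its own blocks plus a
few k × k aggregates — and the rewritten iteration is *mathematically
identical* to the serial one.  With a fixed reduction order the parallel
engine is even bit-for-bit identical to the single-process run, for any
worker count.

## Worked example

```python
import numpy as np
import blocknmtf as b

# a 200x150 matrix with 4 planted row clusters and 3 column clusters
X, row_truth, col_truth = b.make_cocluster(
    b.PlantedModel(n=200, m=150, k1=4, k2=3, noise_sd=0.08, seed=0)
)

cfg = b.FitConfig(k1=4, k2=3, variant="orthogonal", seed=0,
                  max_iter=600, tol=0.0, check_every=100)
grid = b.partition_matrix(X, 2, 2)

serial = b.fit_serial(X, cfg)
blocked = b.fit_blockwise(X, cfg, grid)
parallel = b.run_parallel(X, cfg, grid, p=4)

print("serial vs 2x2 block max |Δ|:",
      np.max(np.abs(serial.factors.U - blocked.factors.U)))
print("4 workers bit-identical:",
      np.array_equal(blocked.factors.U, parallel.factors.U))

res, cc = b.interpret.fit_coclusters(X, cfg, restarts=5)
from sklearn.metrics import adjusted_rand_score
print("row-cluster ARI:", adjusted_rand_score(row_truth, cc.row_labels))
print("top co-cluster:", cc.ranked_pairs[0])
```

Output:

```
serial vs 2x2 block max |Δ|: 2.636779683484747e-16
4 workers bit-identical: True
row-cluster ARI: 1.0
top co-cluster: (0, 1, 77.52699296738344)
```

The first line shows the serial/block-wise agreement (floating-point
noise only); the second the parallel determinism contract; the ARI of
1.0 means the argmax readout of **U** recovered the planted row clusters
exactly; the last line is the strongest row-cluster/column-cluster
interaction read off **S**.

A command-line entry point runs the same pipeline on files:

```sh
blocknmtf --input X.mtx --format matrixmarket --k1 3 --k2 2 \
          --blocks 2x2 --workers 4 --seed 7 --output-dir out/
```

writing factor matrices, cluster labels, ranked co-cluster pairs and a
JSON run log.

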