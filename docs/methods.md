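# Methods

## Model and objective

Given a non-negative data matrix X (n rows = instances, m columns =
features), non-negative matrix tri-factorization (NMTF) seeks

    X ≈ U S Vᵀ,  U ≥ 0 (n × k1),  S ≥ 0 (k1 × k2),  V ≥ 0 (m × k2),

minimising F(U,S,V) = ‖X − U S Vᵀ‖²_Fro.  k1 and k2 are the numbers of
latent vectors for the row and column space; useful models have
k1, k2 ≪ min(n, m).  The factors are learned by multiplicative update
rules, each multiplying a factor elementwise by a ratio of non-negative
gradient terms:

    U ← U ∘ (X V Sᵀ) / (U S VᵀV Sᵀ)
    V ← V ∘ (Xᵀ U S) / (V Sᵀ UᵀU S)
    S ← S ∘ (Uᵀ X V) / (UᵀU S VᵀV)

The orthogonal variant targets UᵀU = I and VᵀV = I (non-negative
orthogonal columns have disjoint supports, so each row loads on
essentially one latent vector — the property that makes argmax cluster
readout meaningful) and multiplies by the square root of a guarded
ratio:

    U ← U ∘ sqrt((X V Sᵀ) / (U Uᵀ X V Sᵀ))
    V ← V ∘ sqrt((Xᵀ U S) / (V Vᵀ Xᵀ U S))
    S ← S ∘ sqrt((Uᵀ X V) / (UᵀU S VᵀV))

Non-negativity is preserved by construction; entries that are exactly
zero stay zero (multiplicative-zero semantics).  The non-orthogonal
rules empirically never increase the objective (verified to 1e-12
relative slack over hundreds of runs in the test suite); the orthogonal
rules are a heuristic without a monotonicity guarantee and are checked
only for overall improvement.

### Assumptions and caveats

* The factorisation is not unique: U → U D, S → D⁻¹ S leaves the model
  unchanged for any positive diagonal D.  Interpretation-sensitive
  readouts should use the orthogonal variant.
* Multiplicative updates find local optima.  Every fitting entry point
  is deterministic given a seed; `interpret.fit_coclusters` adds
  restarts scored by the final objective (no ground truth involved).
* Stationarity of the orthogonal rules at an exact factorisation holds
  only when the factorisation actually satisfies the orthogonality
  constraint; the synthetic module provides `make_exact_orthogonal` for
  exactly this fixture.

## Block-wise formulation

X is split into an N × M grid of contiguous blocks X^(i,j); U inherits
the N row bands, V the M column bands; S is never partitioned.  Each
serial rule rewrites exactly over the blocks, e.g. the i-th band of the
U numerator X V Sᵀ is Σⱼ X^(i,j) (V^(j) Sᵀ), and every denominator needs
only small k × k aggregates:

* gram_u = Σᵢ (U^(i))ᵀ U^(i)  and  gram_v = Σⱼ (V^(j))ᵀ V^(j),
* the cross term uxv = Σᵢⱼ (U^(i))ᵀ X^(i,j) V^(j),
* for the orthogonal U rule, A = Σᵢ (U^(i))ᵀ P^(i) with P^(i) the band
  numerator (symmetrically B for V).

The block-wise orthogonal rules are implemented as the exact block
rewriting of the serial orthogonal rules — band numerator over band
times the global aggregate — which is what makes the assembled result
equal the serial one.

Equality is exact in real arithmetic; numerically the suite enforces
1e-10 (single sweep) and 1e-8 (50 iterations) max-abs agreement.  Two
conventions make a 1×1 grid *bit-identical* to the serial path:

* every expression is evaluated with one fixed association order in
  both paths (e.g. U @ ((S @ gram_v) @ Sᵀ), and the orthogonal
  denominators as U @ (Uᵀ @ num) to avoid n × n intermediates);
* partial sums accumulate in ascending block index, row-major for uxv.

Within one iteration the update order is U, then V, then S, each rule
consuming the freshest factors; aggregates are recomputed at the point
each rule consumes them.

## Partitioning

Dense matrices: row band i spans rows ⌊i·n/N⌋ … ⌊(i+1)·n/N⌋ (likewise
columns), so any two band sizes differ by at most one.  Sparse
matrices: bands are chosen by prefix sums of per-row (per-column)
nonzero counts — the b-th boundary sits after the first index whose
cumulative count reaches b·nnz/N — so each band carries roughly equal
stored entries, the quantity that determines per-worker work.
Balancing is marginal (rows and columns independently); there is no
joint block-level optimisation and no reordering.  Rows or columns with
zero nonzeros stay in whichever band their index falls into; boundaries
are nudged minimally when needed so no band is empty, and a matrix with
fewer nonempty rows than requested bands is rejected.  All intervals
are 0-based and half-open.

## Parallel engine

One worker process owns one block (p = N·M; p = 1 falls back to the
single-process block-wise path).  Each worker holds replicas of its row
band of U, its column band of V, and all of S.  An iteration runs in
barrier-aligned stages: block-local partial products; reduction of the
k-dimensional aggregates over workers *in ascending block index* via a
coordinator; broadcast of the reduced aggregates; local replica
updates.  Factor bands themselves never travel — replicas of a band are
updated redundantly from identical aggregate inputs, which yields
identical bits and keeps payloads k-dimensional.  Consequently an N×1
grid exchanges no U-side payloads at all and a 1×M grid no V-side
payloads, mirroring how tall matrices favour row-wise and wide matrices
column-wise partitioning.

Because the reduction order is fixed, the parallel result is
bit-identical to the single-process block-wise run for any worker
count, and repeated runs with one seed are bit-identical to each other.
Workers are OS processes exchanging pickled arrays over pipes through
the coordinator (a star topology); the `StagePlan` from `build_plan`
records the logical producer→consumer pattern of every payload for
inspection and logging.  Convergence is judged centrally: at check
iterations band owners ship their replicas to the coordinator, which
evaluates the objective and broadcasts a stop flag.

## Interpretation

`assign_clusters` labels row i by argmax of U[i, :] and column j by
argmax of V[j, :] (ties to the lowest index; all-zero rows are labelled
0 and flagged), reads interaction scores from S and ranks cluster pairs
by descending score.  `fit_coclusters` wraps this with restarted
orthogonal fits (default 5 restarts, seeds seed+0 … seed+r−1), keeping
the restart with the lowest final objective — the standard remedy for
multiplicative local minima, and selectable without ground truth.

`select_rank` holds out a seeded random fraction of entries, fits each
candidate (k1, k2) on the observed cells only via mask-weighted
multiplicative rules (masked cells enter neither numerators nor
denominators; an orthogonal masked mode exists as well), represents
each candidate by its best-of-restarts fit *scored on observed cells
only*, and returns the candidate with the smallest squared error on the
held-out cells.  A structural limitation is worth knowing: the model
capacity of an NMTF pair is governed by min(k1, k2) — rank(U S Vᵀ) ≤
min(k1, k2), and any cone generated by several non-negative rays inside
a 2-dimensional non-negative plane equals the cone of its two outer
rays.  Candidate pairs sharing the same min(k1, k2) therefore describe
*identical* sets of reconstructions, their held-out errors tie up to
optimizer noise, and no reconstruction-based criterion can separate
them (e.g. (3,2) against (2,2)).  Rank selection is reliable exactly
when the candidates differ in min(k1, k2): on planted (3,3) co-cluster
data against {(2,2), (3,3), (5,5)} the held-out error recovers (3,3) in
20/20 seeded trials, the under-sized candidate losing by bias and the
over-sized one by variance.

## Synthetic data

* `make_exact` draws strictly positive factors (uniform [0.1, 1)) and
  returns X = U₀S₀V₀ᵀ — the zero-error fixture.
* `make_exact_orthogonal` builds column-orthonormal non-negative U and
  V (disjoint supports from a balanced label assignment, then column
  normalisation) — the stationarity fixture for the orthogonal rules.
* `make_cocluster` plants row and column labels (every cluster
  non-empty) and sets X_ij = block_means[r_i, c_j] plus zero-truncated
  Gaussian noise (scipy's truncnorm, so non-negativity holds without
  piling mass at zero and block-mean ordering is preserved).  Default
  noise_sd = 0.08 — 10% of the default block-mean spread (0.6 vs 1.4).
  Default block means give each row cluster a distinct subset of
  elevated column clusters (singletons, then pairs), levels 0.6/1.4
  with ±5% multiplicative jitter.  The subset scheme is an
  identifiability guard: when k1 > k2 the signal matrix has rank ≤ k2,
  and a planted row-mean vector that is a conic combination of the
  others cannot be separated by *any* factorisation method — a
  recovery test on such data would measure luck.  With the default
  pattern the (4,3) and (3,3) configurations used in the tests have
  every block-mean row and column an extreme ray.  Optional
  sparsification keeps each entry with probability `density`.
* `make_skewed_sparse` allocates an exact total number of nonzeros to
  rows with power-law weights (r+1)^−skew (overflow past the m-per-row
  cap is reassigned in descending weight order so concentration
  survives), uniform positive values, distinct column positions per
  row.

What the generators do *not* emulate: real marginal distributions
(methylation beta values, count overdispersion), correlated noise,
or network topology.  Passing recovery tests therefore demonstrates
correctness of the algorithms on data satisfying the model's own
assumptions, not performance on any particular biological dataset.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-12 | elementwise lower guard on update denominators, `max(den, eps)`; preserves multiplicative-zero semantics when sparse rows/columns zero a denominator |
| `tol` | 1e-5 | relative objective change between consecutive recorded values below which the run stops |
| `check_every` | 10 | iterations between objective evaluations |
| `max_iter` | 200 | hard iteration cap |
| `init_scale` | sqrt(mean(X)/(k1·k2)) | upper bound of the uniform (0, scale] initial factors, so E[U S Vᵀ] is on the scale of X |
| `restarts` | 5 | restarted fits in `fit_coclusters` / `select_rank`, scored without ground truth |

Initial factors are strictly positive (uniform on (0, scale]) so no
entry starts dead; the draw order U, S, V is fixed, making a seed fully
determine a run.  All computation is double precision.  Objective
values for sparse X use the Gram expansion ‖X‖² − 2·tr(Sᵀ UᵀXV) +
tr(UᵀU S VᵀV Sᵀ), clamped at zero against cancellation.

Problem sizes in the test-suite and acceptance runs (60×40 to 200×150,
ranks 2–6, 20-seed batteries) were chosen so the full battery completes
in a few minutes on one CPU while leaving each property's failure modes
(local minima, load imbalance, overfitting) clearly visible.

## Known limitations

* One block per worker; no multi-block scheduling, no rebalancing
  during a run, no overlap of communication and computation.
* The orthogonality constraint is enforced only asymptotically by the
  update dynamics, never projected; UᵀU can remain visibly far from I
  on hard instances.
* Masked (held-out) fitting densifies the matrix; rank selection is
  intended for dense or small sparse inputs.
* Candidate rank pairs sharing min(k1, k2) are indistinguishable by
  held-out reconstruction error (see Interpretation above).
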