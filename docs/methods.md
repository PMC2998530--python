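# Methods

`lowdim` embeds a samples × genes expression matrix X ∈ ℝ^(N×D) (N samples,
D features, typically D ≫ N) into a low-dimensional space Y ∈ ℝ^(N×d) with
seven unsupervised methods, and assesses the embeddings with a
classification / cluster-validity / noise benchmark.  This note records the
model choices, conventions and their rationale.

## Embedding algorithms

All methods reduce to an eigenproblem; the shared conventions are:

* **Eigenvalue floor.** Eigenvalues with |λ| < 1e-10 · max|λ| are treated as
  zero (rank decisions, zero-padding of missing coordinates).
* **Sign convention.** Every eigenvector-derived coordinate column is
  flipped so its largest-magnitude entry is positive.  Eigenvectors are only
  defined up to sign; fixing it makes output reproducible across solvers.
* **Neighbor graphs.** k-nearest-neighbor selection breaks distance ties
  toward the smaller sample index; graphs are symmetrized by edge union.
  Edge weights are Euclidean distances.
* **Disconnected graphs** (Isomap, Laplacian Eigenmaps, MVU): the largest
  connected component is embedded, the dropped sample ids are recorded on
  the result, and a warning is emitted.  LLE tolerates disconnected weight
  graphs without special handling (its bottom eigenvectors then mix
  component indicators; with the recommended k ≥ 4 on real data this does
  not arise in practice and is left to the caller).

**PCA** is computed through the N × N route: the feature-centered Gram
matrix (1/N)·X_c·X_c′ is eigendecomposed and the projection onto axis w_j is
recovered as √(N·λ_j)·u_j.  This is algebraically identical to
covariance-route PCA (oracle-tested) but avoids ever forming the D × D
covariance matrix, which is the only practical option for microarray-sized
D.  Degenerate input (zero variance) yields all-zero coordinates with a
warning rather than an error.

**Kernel PCA** uses the Gaussian kernel K(x_i, x_j) = exp(−‖x_i−x_j‖²/σ²).
Note the denominator σ², not the 2σ² that is also common; parameter values
quoted elsewhere in this package assume this parameterization.  The kernel
matrix is double-centered before eigendecomposition — the feature-space
analogue of mean subtraction, required for the optimization to match PCA's
— and coordinates are eigenvectors scaled by √λ, so Euclidean geometry in
the embedding equals feature-space projections.

**Isomap** composes neighbor graph → shortest-path (geodesic) distances →
classical (Torgerson) MDS.  Negative eigenvalues of the doubly-centered
squared-distance matrix — geodesic matrices are generally not Euclidean —
are dropped; if fewer than d positive eigenvalues exist, the remaining
columns are zero-padded with a warning.  The *modified* variant links every
sample to its k/2 nearest and k/2 farthest peers (k must be even), a
heuristic that keeps widely separated clusters from collapsing onto each
other in the embedding.

**LLE** first solves, per sample, the constrained least squares
min_w ‖x_i − Σ_j w_j x_nbr(j)‖² with Σ_j w_j = 1.  When k exceeds the
effective local dimension (numerical rank of the local Gram matrix) the
problem is singular and the Gram diagonal is conditioned with
1e-3 · trace/k — the standard fix; because the term scales with the data,
weights remain exactly invariant to global rescaling.  The embedding is the
bottom d+1 eigenvectors of (I−W)′(I−W) with the constant eigenvector
discarded, then centered and scaled to unit per-column variance (the usual
normalization; the cost function alone fixes Y only up to affine maps).

**Laplacian Eigenmaps** builds a Gaussian-weighted kNN graph and solves the
generalized problem L v = λ Deg v (L = Deg − W), discarding the constant
eigenvector (λ < 1e-10).  Coordinates are the d smallest nontrivial
generalized eigenvectors, Deg-orthonormal as returned by the symmetric
reduction.

**Diffusion Maps** row-normalizes the full Gaussian kernel into a Markov
matrix Ŵ and uses its right eigenvectors: coordinates λ_k^t ψ_k(i),
k = 1..d, skipping the trivial pair λ₀ = 1.  The eigenvectors are scaled so
that Euclidean distance in the *full* (d = N−1) embedding equals the
diffusion distance
D_t(i,j) = √( Σ_l (Ŵ^t(i,l) − Ŵ^t(j,l))² / π_l ),
where π is the stationary distribution of the kernel random walk
(π_i = d_i / Σ d, d_i the unnormalized kernel row sum).  The inverse-π
weighting is what makes this identity exact (it is pinned by a test), and
the distance is exposed as a true metric, i.e. with the square root.
Default diffusion time t = 1.

**MVU** maximizes total pairwise scatter subject to exact preservation of
squared neighbor distances — in Gram form: maximize trace(K) over PSD K with
Σ_ij K_ij = 0 and K_ii − 2K_ij + K_jj = ‖x_i−x_j‖² per neighbor edge.  The
library builds this SDP itself and delegates to a pluggable solver
(register one or pass a callable; absent a solver, MVU raises an explicit
error).  The bundled `reference_solver` is a first-order augmented
Lagrangian on the factorization K = VV′ (L-BFGS inner loop, multiplier
updates outer, warm-started from MDS on graph shortest paths).  It reaches
~1e-9 relative constraint violation on instances of tens to a few hundred
samples; it is not intended for large N, where the 2-hour class of
interior-point solvers the literature uses would be appropriate anyway.

## Cluster validity and hypothesis testing

The **Davies-Bouldin index** is evaluated literally: cluster centers μ_i,
within-cluster scatter d_i = mean ‖x − μ_i‖, pair ratio
R_ij = (d_i + d_j)/‖μ_i − μ_j‖, and DB = mean_i max_j R_ij.  Lower is
better.  Singleton clusters are legal (d_i = 0); two clusters with identical
centers are an error (R undefined).  The benchmark computes DB at fixed
target dimensions 2, 3, 5 and 10.

The **Wilcoxon signed-rank test** drops zero differences, assigns midranks
to ties, and for n ≤ 25 retained pairs computes the exact null distribution
of the positive-rank sum by dynamic programming over the (doubled, integer)
ranks — equivalent to enumerating all 2^n sign assignments, and valid under
ties, which is why the test is implemented here rather than delegated.
Above n = 25 a normal approximation with tie-corrected variance and
continuity correction is used.  Two-sided p-values are 2·min(P≤, P≥) capped
at 1.  p-values are deliberately *not* adjusted for multiple testing; the
comparison runner reports raw per-pair values.

A note on invariances: signed-rank p-values are invariant under positive
*affine* transforms applied to both samples (tested), but not under general
monotone transforms, which can reorder the absolute differences.

## The expression simulator

`simulate_expression` emulates a two-class microarray experiment:

| parameter | default | meaning |
|---|---|---|
| n_samples | 50 | samples (first half = class 1, second half = class 0) |
| n_genes | 10,000 | features, standard normal marginals |
| rho | 0.2 | within-block correlation (0 across blocks) |
| block_size | 50 | genes per covariance block |
| n_diff | 0 | differentially expressed genes (swept 10–500 in the study) |
| shift | 0.6 | constant added to differential genes for class 1 |
| noise_variance | 0 | post-scaling additive Gaussian noise |

Block correlation uses the single-factor construction
g = √ρ·z_block + √(1−ρ)·ε, which gives the exact compound-symmetry
covariance in O(N·D) time (no per-block Cholesky).  Differential genes are
drawn uniformly without replacement; one seed governs everything, so the
generator is a pure function of its configuration.

The noise protocol scales the whole matrix (globally, not per feature —
the point is to put datasets with different dynamic ranges on one scale)
onto [0, 1] and then adds i.i.d. N(0, variance) noise; the result is not
re-scaled afterwards, so a given variance means the same corruption level
everywhere.

What the generator does *not* emulate: probe-level artifacts, intensity-
dependent variance, normalization pipeline effects, unbalanced classes, or
correlation between differential status and block membership.  Passing
benchmarks on simulated data therefore demonstrate behavior under clean
compound-symmetry noise with an additive class effect, not performance on
any particular platform's data.

A calibration worth knowing: with shift 0.6 and 25 + 25 samples the
per-gene two-sample t statistic has noncentrality ≈ 2.1, so only about half
of 300 differential genes rank in the top 300 by |t| — the simulated signal
is intentionally subtle, which is exactly why unsupervised 2-D embeddings
separate the classes only partially (see below).

The **Swiss Roll** generator returns (t·cos t, h, t·sin t) with t uniform on
[1.5π, 4.5π] and h uniform on [0, 21] (conventional ranges), plus the latent
(t, h) for manifold-recovery checks.

## The benchmark protocol

1. **Parameter selection.**  Candidate grids: d ∈ 2..15, k ∈ 4..16, and
   eight log-spaced kernel widths σ ∈ {0.1, 1, 10, 100, 1e3, 1e4, 1e5, 5e5}
   (the printed range endpoints are honored; the interior realization is a
   log grid).  Each candidate embeds the complete dataset once and is scored
   by leave-one-out SVM accuracy; equal accuracies resolve to the lowest d,
   then k, then σ (simplest representation).  Embeddings never see labels.
2. **Randomization classification.**  One hundred stratified 2/3-train
   splits (per-class train count = floor(2/3·n_class)); (C, γ) selected on
   each training set by loo-cv grid search over C ∈ {0.1, 1, 10, 100} ×
   γ ∈ {1e-3 … 1e2}; the median test accuracy is the summary.  Round r uses
   a counter-derived seed (base, r), so individual rounds are reproducible.
3. **Cluster validation.**  Davies-Bouldin at d ∈ {2, 3, 5, 10}, re-embedded
   with the selected neighbor/kernel parameter.

The protocol applies dimension reduction to the complete dataset *before*
cross-validation, i.e. held-out samples shape the embedding geometry.  This
is deliberate (the embedding is the object under study, and all methods
share the bias) but means absolute accuracies are optimistic; only
between-method comparisons should be interpreted.

**SVM model selection in the simulation study.**  Embedding coordinate
scales differ by orders of magnitude between methods (eigenvalue-scaled PCA
or Isomap axes versus unit-variance LLE output), so a fixed γ grid
systematically underfits some methods.  The simulation study therefore uses
C ∈ {1, 10, 100} crossed with the median heuristic γ ∈ {0.1, 1, 10} /
median(pairwise squared distance), which is equivalent to applying a fixed
grid to globally rescaled coordinates and was validated against a much
finer fixed grid (agreement within ~0.04 accuracy at a quarter of the
cost).  The full printed grid remains the default for the randomization
protocol.

**Problem sizes.**  The simulation study sweeps the differential-gene count
over {10, 50, 100, 150, 200, 300, 400, 500} with 20 replicate datasets per
count at the full generator conditions (50 × 10,000), embedding with PCA,
LLE and Isomap at d = 2 and choosing k from the sweep {4, 8, 12, 16}.  The
noise study uses 12 replicates at n_diff = 300 and variances {0, 0.1, 0.2}.

## What the simulation study shows

Under these conditions the unsupervised 2-D accuracies are moderate (the
class-mean direction carries an eigenvalue ‖δ‖²/4 ≤ 45 even at 500
differential genes, against sample-Gram noise eigenvalues around 200, so no
unsupervised method can isolate it cleanly in two dimensions — a supervised
projection separates the same data perfectly).  The scientifically
meaningful and reproducible facts are *relative*: LLE and Isomap beat PCA
at low differential-gene counts, and PCA needs well over 150 differential
genes before its mean 2-D accuracy comes within two percentage points of
the better nonlinear method.  `scripts/acceptance.py` recomputes exactly
this crossover count.

## Known limitations

* No out-of-sample extension: every embedding is transductive over the
  given matrix (a new sample means re-embedding).
* The reference MVU solver is first-order and small-N only.
* Exact Wilcoxon is O(n²·max-rank-sum) via DP — fine for the tens of pairs
  it is meant for.
* The CLI reads uncompressed TSV only; platform-specific microarray formats
  and normalization are out of scope.
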