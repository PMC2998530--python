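# lowdim

Unsupervised dimension reduction and benchmarking for the visualization of
gene-expression data.

Two- and three-dimensional scatter plots are a standard first look at a
microarray or expression experiment: they reveal class structure, outliers
and quality problems.  The mapping from D ≈ 10⁴ features down to d = 2–3 is
usually PCA, but linear projections can miss class structure that nonlinear
manifold methods capture.  `lowdim` implements seven unsupervised
embeddings behind one interface —

| method | idea | free parameters |
|---|---|---|
| PCA | variance-maximizing linear axes (computed via the N×N Gram matrix) | d |
| KPCA | PCA in Gaussian-kernel feature space, K = exp(−‖x−x′‖²/σ²) | d, σ |
| Isomap (IM) | classical MDS on graph-geodesic distances | d, k |
| IM(mod) | Isomap linking k/2 nearest *and* k/2 farthest neighbors | d, k |
| LLE | preserve local affine reconstruction weights, Σ_j W(i,j) = 1 | d, k |
| Laplacian Eigenmaps (LEM) | minimize Σ ‖y_i−y_j‖² W(i,j) on the kNN graph | d, k, σ |
| Diffusion Maps (DM) | spectral embedding λ^t ψ of the kernel Markov chain | d, σ, t |
| MVU | maximize scatter s.t. exact neighbor distances (an SDP) | d, k |

— plus the machinery to judge them: leave-one-out and randomization SVM
classification, the Davies-Bouldin cluster-validity index
DB = (1/M) Σ_i max_j (d_i+d_j)/‖μ_i−μ_j‖, an exact Wilcoxon signed-rank
test for paired method comparisons, a calibrated synthetic microarray
generator (block-diagonal gene covariance, additive class shifts, a
controlled noise protocol) and a Swiss-Roll fixture.

It is a library first (`import lowdim`) with a thin CLI (`lowdim`) on top,
aimed at computational biologists who want to compare embeddings of their
own two-class expression matrices or study method behavior on simulated
data.

## Worked example

Simulate a 50-sample × 10,000-gene two-class dataset with 300 differential
genes, embed it three ways, and score the embeddings:

```python
import numpy as np
from lowdim import (SimulationConfig, simulate_expression, pca_embed,
                    lle_embed, isomap_embed, davis_bouldin,
                    SVMClassifier, adaptive_gammas, grid_loo_accuracy)

X, diff_genes = simulate_expression(SimulationConfig(n_diff=300, seed=7))
labels = X.label_vector()
clf = SVMClassifier()
for emb in (pca_embed(X, 2), lle_embed(X, 2, 12), isomap_embed(X, 2, 8)):
    acc, C, gamma = grid_loo_accuracy(emb.coords, labels, clf,
                                      Cs=(1, 10, 100),
                                      gammas=adaptive_gammas(emb.coords))
    db = davis_bouldin(emb.coords, labels).db_index
    print(f"{emb.method:4s}  loo-cv accuracy {acc:.2f}   DB-index {db:.2f}")
```

```
PCA   loo-cv accuracy 0.72   DB-index 2.24
LLE   loo-cv accuracy 0.68   DB-index 2.09
IM    loo-cv accuracy 0.64   DB-index 2.77
```

Read: with 300 of 10,000 genes shifted by +0.6, a two-dimensional
embedding lets a Gaussian-kernel SVM classify held-out samples well above
the 50% chance rate; lower DB means more compact, better separated label
clusters.  The simulated signal is deliberately subtle, so single-dataset
scores are noisy — on this particular seed PCA happens to lead, while over
20 replicates the nonlinear methods are reliably ahead at this setting
(mean accuracies 0.75 Isomap / 0.73 LLE / 0.70 PCA; see the study below).
Never interpret one simulated dataset; sweep and replicate.

The same from the shell:

```sh
lowdim simulate --out-prefix sim --n-diff 300 --seed 7
lowdim embed --input sim_expression.tsv --method lle --dim 2 --k 12 \
             --output sim_lle.tsv --labels sim_labels.tsv --plot sim_lle.png
lowdim dbindex --embedding sim_lle.tsv --labels sim_labels.tsv
```

Expression matrices are tab-separated with genes in rows by default
(`--orientation` to override); labels are a two-column TSV.  The
`benchmark`, `noise` and `simstudy` subcommands run the full assessment
protocol from a plain-text config file; see `docs/methods.md` for the
protocol and all conventions.

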