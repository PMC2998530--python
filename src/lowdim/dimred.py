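"""Unsupervised embedding algorithms.

Seven methods over a samples x genes matrix: PCA (through the N x N Gram
route), Kernel PCA with a Gaussian kernel, Isomap and its
nearest-plus-farthest-neighbor modification, Locally Linear Embedding,
Laplacian Eigenmaps and Diffusion Maps.  Maximum Variance Unfolding lives in
:mod:`lowdim.mvu` because it needs a semidefinite-program solver.

Conventions shared by every eigenvector-derived coordinate column:

* eigenvalues with ``|lambda| < 1e-10 * max|lambda|`` are treated as zero;
* each column's sign is flipped so its entry of largest absolute value is
  positive (reproducible output across eigensolvers);
* nearest-neighbor ties are broken in favor of the smaller sample index, and
  neighbor graphs are symmetrized by edge union.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from numpy.linalg import matrix_power
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .types import Embedding, ExpressionMatrix, KernelParams, NeighborGraph, ValidationError

EIG_REL_TOL = 1e-10


class DisconnectedGraphWarning(UserWarning):
    """Emitted when samples are dropped because the neighbor graph is disconnected."""


# ---------------------------------------------------------------------------
# shared numerics


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    V = np.array(V, dtype=float)
    for c in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, c])))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
    return V


def pairwise_sq_distances(values: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances via the Gram matrix."""
    G = values @ values.T
    sq = np.diag(G).copy()
    D2 = sq[:, None] + sq[None, :] - 2.0 * G
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return D2


def _as_values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _sample_ids(X, n: int) -> list:
    if isinstance(X, ExpressionMatrix):
        return list(X.sample_ids)
    return [f"S{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# PCA / Kernel PCA


def center_features(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature column's mean."""
    return X.with_values(X.values - X.values.mean(axis=0))


def pca_embed(X: ExpressionMatrix, d: int) -> Embedding:
    """Principal components computed through the N x N route.

    The feature-centered data ``X_c`` is never used to form the D x D
    covariance matrix; instead the scaled Gram matrix ``(1/N) X_c X_c'`` is
    eigendecomposed and the axis projections are recovered from its
    eigenpairs, which is mathematically identical to covariance-route PCA
    (and cheap when D >> N, the microarray regime).
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= d <= n - 1:
        raise ValidationError(f"target dimension d={d} outside [1, N-1]=[1, {n - 1}]")
    Xc = vals - vals.mean(axis=0)
    G = (Xc @ Xc.T) / n
    lam, U = eigh(G)
    lam, U = lam[::-1], U[:, ::-1]
    tol = EIG_REL_TOL * max(abs(lam[0]), abs(lam[-1]), 1e-300)
    lam_d = np.where(lam[:d] > tol, lam[:d], 0.0)
    if not lam_d.any():
        warnings.warn("data has zero variance; returning all-zero coordinates")
    # projection onto axis w_j equals sqrt(N * lambda_j) * u_j
    coords = U[:, :d] * np.sqrt(n * lam_d)
    coords = _fix_signs(coords)
    return Embedding(coords, "PCA", {"d": d}, _sample_ids(X, n))


def _gaussian_kernel(values: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-pairwise_sq_distances(values) / sigma**2)


def kpca_embed(X: ExpressionMatrix, d: int, kp: KernelParams) -> Embedding:
    """Kernel PCA with the Gaussian kernel exp(-||x_i-x_j||^2 / sigma^2).

    The kernel matrix is double-centered (the feature-space analogue of mean
    subtraction) before eigendecomposition; coordinate column j is the j-th
    eigenvector scaled by the square root of its eigenvalue, so Euclidean
    geometry in the embedding matches feature-space projections.
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= d <= n - 1:
        raise ValidationError(f"target dimension d={d} outside [1, N-1]=[1, {n - 1}]")
    K = _gaussian_kernel(vals, kp.sigma)
    Kc = _double_center(K)
    lam, V = eigh(Kc)
    lam, V = lam[::-1], V[:, ::-1]
    tol = EIG_REL_TOL * max(abs(lam).max(), 1e-300)
    lam_d = np.where(lam[:d] > tol, lam[:d], 0.0)  # drop near-zero eigenvalues
    coords = _fix_signs(V[:, :d] * np.sqrt(lam_d))
    return Embedding(coords, "KPCA", {"d": d, "sigma": kp.sigma}, _sample_ids(X, n))


def _double_center(M: np.ndarray) -> np.ndarray:
    r = M.mean(axis=1, keepdims=True)
    c = M.mean(axis=0, keepdims=True)
    return M - r - c + M.mean()


# ---------------------------------------------------------------------------
# neighbor graphs and Isomap


def build_neighbor_graph(X, k: int, mode: str = "nearest") -> NeighborGraph:
    """Link each sample to its k nearest (or k/2 nearest + k/2 farthest) peers.

    Weights are Euclidean distances; the result is symmetrized by edge union
    (an edge exists if either endpoint selected the other).  Distance ties are
    broken in favor of the smaller sample index.
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= k <= n - 1:
        raise ValidationError(f"neighbor count k={k} outside [1, N-1]=[1, {n - 1}]")
    if mode not in ("nearest", "nearest_farthest"):
        raise ValidationError(f"unknown neighbor mode {mode!r}")
    if mode == "nearest_farthest" and k % 2 != 0:
        raise ValidationError("nearest_farthest mode requires an even k (k/2 of each kind)")
    D = np.sqrt(pairwise_sq_distances(vals))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")  # stable: smaller index wins ties
        order = order[order != i]
        if mode == "nearest":
            sel = order[:k]
        else:
            near = order[: k // 2]
            far_order = np.argsort(-D[i], kind="stable")
            far_order = far_order[far_order != i]
            far = far_order[: k // 2]
            sel = np.concatenate([near, far])
        mask[i, sel] = True
    mask |= mask.T
    np.fill_diagonal(mask, False)
    return NeighborGraph(n_nodes=n, k=k, mode=mode, mask=mask, dist=D)


def geodesic_distances(G: NeighborGraph) -> np.ndarray:
    """Shortest-path distances through the neighbor graph.

    Entries for unreachable pairs are infinite; disconnection is handled by
    the callers (largest-component policy), not here.
    """
    return shortest_path(G.masked_adjacency(), method="auto", directed=False)


def classical_mds(Dist: np.ndarray, d: int) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Eigendecomposes -1/2 J (Dist o Dist) J with J the centering projector;
    coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues.  If fewer than ``d`` positive eigenvalues exist the remaining
    columns are zero and a warning is emitted.
    """
    Dist = np.asarray(Dist, dtype=float)
    n = Dist.shape[0]
    if Dist.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not np.isfinite(Dist).all():
        raise ValidationError("distance matrix must be finite (graph disconnected?)")
    if not np.allclose(Dist, Dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(Dist), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    B = -0.5 * _double_center(Dist * Dist)
    lam, V = eigh(B)
    lam, V = lam[::-1], V[:, ::-1]
    tol = EIG_REL_TOL * max(abs(lam).max(), 1e-300)
    lam_d = lam[:d].copy()
    n_pos = int((lam_d > tol).sum())
    if n_pos < d and abs(lam).max() > 0:
        warnings.warn(
            f"only {n_pos} positive eigenvalues available for d={d}; "
            "padding remaining coordinates with zeros"
        )
    lam_d = np.where(lam_d > tol, lam_d, 0.0)
    return _fix_signs(V[:, :d] * np.sqrt(lam_d))


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Indices of the largest connected component of a boolean adjacency."""
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    if n_comp == 1:
        return np.arange(mask.shape[0])
    sizes = np.bincount(labels)
    keep = int(np.argmax(sizes))  # ties: smallest component label
    return np.flatnonzero(labels == keep)


def _connected_subset(X: ExpressionMatrix, k: int, mode: str):
    """Restrict X to samples whose neighbor graph is connected.

    Returns (X_subset, graph, dropped_ids).  The graph is rebuilt on the kept
    samples (which can in principle disconnect again, hence the loop).
    """
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix.from_array(_as_values(X))
    dropped: list = []
    for _ in range(X.n_samples):
        G = build_neighbor_graph(X, k, mode)
        keep = largest_component(G.mask)
        if keep.size == X.n_samples:
            if dropped:
                warnings.warn(
                    f"neighbor graph disconnected; embedding the largest component "
                    f"({X.n_samples} samples), dropped: {dropped}",
                    DisconnectedGraphWarning,
                )
            return X, G, tuple(dropped)
        dropped.extend(s for i, s in enumerate(X.sample_ids) if i not in set(keep.tolist()))
        X = X.subset_samples(keep.tolist())
    raise ValidationError("could not obtain a connected neighbor graph")


def isomap_embed(X: ExpressionMatrix, d: int, k: int, modified: bool = False) -> Embedding:
    """Isomap: neighbor graph -> geodesic distances -> classical MDS.

    With ``modified=True`` the graph links each sample to its k/2 nearest and
    k/2 farthest peers, a variant meant to keep well-separated clusters from
    collapsing onto each other.  A disconnected graph is reduced to its
    largest connected component (dropped sample ids are recorded on the
    result).
    """
    mode = "nearest_farthest" if modified else "nearest"
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix.from_array(_as_values(X))
    Xs, G, dropped = _connected_subset(X, k, mode)
    n = Xs.n_samples
    if not 1 <= d <= n - 1:
        raise ValidationError(f"target dimension d={d} outside [1, N-1]=[1, {n - 1}]")
    DG = geodesic_distances(G)
    coords = classical_mds(DG, d)
    method = "IM_MOD" if modified else "IM"
    return Embedding(coords, method, {"d": d, "k": k}, list(Xs.sample_ids), dropped)


# ---------------------------------------------------------------------------
# Locally Linear Embedding


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    nbrs = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        nbrs[i] = order[order != i][:k]
    return nbrs


def lle_weights(X, k: int) -> csr_matrix:
    """Local reconstruction weights: each sample as an affine combination of
    its k nearest neighbors.

    Row i solves ``min_w w' G_i w`` subject to ``sum(w) = 1`` where
    ``G_i = (x_i - x_nbrs)(x_i - x_nbrs)'`` is the local Gram matrix.  When k
    exceeds the effective local dimension (numerical rank of ``G_i``) the
    diagonal is conditioned with ``1e-3 * trace(G_i)/k`` before solving.
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= k <= n - 1:
        raise ValidationError(f"neighbor count k={k} outside [1, N-1]=[1, {n - 1}]")
    D = np.sqrt(pairwise_sq_distances(vals))
    nbrs = _knn_indices(D, k)
    rows, cols, data = [], [], []
    for i in range(n):
        Z = vals[nbrs[i]] - vals[i]
        G = Z @ Z.T
        tr = np.trace(G)
        if tr <= 0.0:
            w = np.full(k, 1.0 / k)  # all neighbors coincide with x_i
        else:
            if np.linalg.matrix_rank(G) < k:
                G = G + np.eye(k) * (1e-3 * tr / k)
            try:
                w = np.linalg.solve(G, np.ones(k))
            except np.linalg.LinAlgError:
                w = np.linalg.lstsq(G, np.ones(k), rcond=None)[0]
            w = w / w.sum()
        rows.extend([i] * k)
        cols.extend(nbrs[i].tolist())
        data.extend(w.tolist())
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def lle_embed(X: ExpressionMatrix, d: int, k: int) -> Embedding:
    """Locally Linear Embedding.

    The embedding minimizes the reconstruction cost
    ``sum_i ||y_i - sum_j W(i,j) y_j||^2`` with the weights held fixed: the
    bottom d+1 eigenvectors of (I-W)'(I-W), discarding the constant one.
    Output columns are centered and scaled to unit variance (the standard
    normalization; the cost itself fixes the embedding only up to affine
    maps).
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= d <= n - 2:
        raise ValidationError(f"target dimension d={d} outside [1, N-2]=[1, {n - 2}]")
    W = lle_weights(vals, k).toarray()
    IW = np.eye(n) - W
    M = IW.T @ IW
    lam, V = eigh(M)
    coords = V[:, 1 : d + 1]  # drop the constant eigenvector (lambda ~ 0)
    coords = coords - coords.mean(axis=0)
    std = coords.std(axis=0)
    std[std < 1e-300] = 1.0
    coords = _fix_signs(coords / std)
    return Embedding(coords, "LLE", {"d": d, "k": k}, _sample_ids(X, n))


# ---------------------------------------------------------------------------
# Laplacian Eigenmaps


def lem_embed(X: ExpressionMatrix, d: int, k: int, kp: KernelParams) -> Embedding:
    """Laplacian Eigenmaps on a Gaussian-weighted kNN graph.

    Minimizes sum_ij ||y_i - y_j||^2 W(i,j) over the neighbor graph, which
    pulls strongly-connected samples together and so implicitly favors
    natural clusters.  Coordinates are the d smallest nontrivial generalized
    eigenvectors of (L, Deg) with L = Deg - W; the constant eigenvector
    (eigenvalue < 1e-10) is discarded.  A disconnected graph is reduced to
    its largest connected component.
    """
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix.from_array(_as_values(X))
    Xs, G, dropped = _connected_subset(X, k, "nearest")
    n = Xs.n_samples
    if not 1 <= d <= n - 2:
        raise ValidationError(f"target dimension d={d} outside [1, N-2]=[1, {n - 2}]")
    W = np.where(G.mask, np.exp(-(G.dist**2) / kp.sigma**2), 0.0)
    deg = W.sum(axis=1)
    L = np.diag(deg) - W
    lam, V = eigh(L, np.diag(deg))
    if lam[0] > 1e-10:
        warnings.warn(f"smallest Laplacian eigenvalue {lam[0]:.3g} is not numerically zero")
    coords = _fix_signs(V[:, 1 : d + 1])
    return Embedding(
        coords, "LEM", {"d": d, "k": k, "sigma": kp.sigma}, list(Xs.sample_ids), dropped
    )


# ---------------------------------------------------------------------------
# Diffusion Maps


def _markov_matrix(values: np.ndarray, sigma: float):
    """Row-normalized Gaussian kernel (a Markov matrix) plus kernel row sums."""
    W = _gaussian_kernel(values, sigma)
    drow = W.sum(axis=1)
    return W / drow[:, None], drow


def dm_embed(X: ExpressionMatrix, d: int, kp: KernelParams) -> Embedding:
    """Diffusion Maps: spectral embedding of the kernel random walk.

    The row-normalized Gaussian kernel W_hat is a Markov matrix; its right
    eigenvectors psi_k (trivial eigenpair lambda_0 = 1, constant psi_0
    skipped) scaled by lambda_k^t give coordinates whose Euclidean geometry
    reproduces the diffusion distance exactly at full dimension d = N-1.
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not 1 <= d <= n - 1:
        raise ValidationError(f"target dimension d={d} outside [1, N-1]=[1, {n - 1}]")
    W = _gaussian_kernel(vals, kp.sigma)
    drow = W.sum(axis=1)
    vol = drow.sum()
    sqrt_d = np.sqrt(drow)
    S = W / np.outer(sqrt_d, sqrt_d)
    lam, Phi = eigh(S)
    lam, Phi = lam[::-1], Phi[:, ::-1]
    # right eigenvectors of W_hat, normalized so that the diffusion-distance
    # identity holds: psi_k = sqrt(vol) * D^{-1/2} phi_k
    psi = Phi / sqrt_d[:, None] * np.sqrt(vol)
    coords = psi[:, 1 : d + 1] * lam[1 : d + 1] ** kp.t
    coords = _fix_signs(coords)
    return Embedding(coords, "DM", {"d": d, "sigma": kp.sigma, "t": kp.t}, _sample_ids(X, n))


def diffusion_distance(X, kp: KernelParams, i: int, j: int) -> float:
    """Diffusion distance between samples i and j after t random-walk steps.

    Compares the two samples' t-step transition profiles, weighting
    coordinate l by the reciprocal of the walk's stationary mass pi_l (so
    agreement in rarely-visited regions counts more).  Returned as a true
    metric, i.e. the square root of the weighted sum of squares.
    """
    vals = _as_values(X)
    n = vals.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise ValidationError(f"sample indices ({i}, {j}) out of range for N={n}")
    What, drow = _markov_matrix(vals, kp.sigma)
    Wt = matrix_power(What, kp.t)
    pi = drow / drow.sum()
    diff = Wt[i] - Wt[j]
    return float(np.sqrt(np.sum(diff * diff / pi)))


# ---------------------------------------------------------------------------
# dispatcher

METHODS = ("PCA", "KPCA", "IM", "IM_MOD", "LLE", "LEM", "DM", "MVU")

#: which free parameters each method takes besides the target dimension
METHOD_AXES = {
    "PCA": (),
    "KPCA": ("sigma",),
    "IM": ("k",),
    "IM_MOD": ("k",),
    "LLE": ("k",),
    "LEM": ("k", "sigma"),
    "DM": ("sigma",),
    "MVU": ("k",),
}


def embed(
    X: ExpressionMatrix,
    method: str,
    d: int,
    k: int | None = None,
    sigma: float | None = None,
    t: int = 1,
    solver=None,
) -> Embedding:
    """Dispatch to one of the seven embedding algorithms by name."""
    method = method.upper()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    needs = METHOD_AXES[method]
    if "k" in needs and k is None:
        raise ValidationError(f"{method} requires a neighbor count k")
    if "sigma" in needs and sigma is None:
        raise ValidationError(f"{method} requires a kernel width sigma")
    if method == "PCA":
        return pca_embed(X, d)
    if method == "KPCA":
        return kpca_embed(X, d, KernelParams(sigma=sigma, t=t))
    if method == "IM":
        return isomap_embed(X, d, k, modified=False)
    if method == "IM_MOD":
        return isomap_embed(X, d, k, modified=True)
    if method == "LLE":
        return lle_embed(X, d, k)
    if method == "LEM":
        return lem_embed(X, d, k, KernelParams(sigma=sigma, t=t))
    if method == "DM":
        return dm_embed(X, d, KernelParams(sigma=sigma, t=t))
    from .mvu import mvu_embed  # local import: optional solver machinery

    return mvu_embed(X, d, k, solver=solver)
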