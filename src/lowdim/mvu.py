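"""Maximum Variance Unfolding behind a pluggable SDP-solver contract.

MVU 'unfolds' a dataset by maximizing the total pairwise scatter of the
embedding while exactly preserving the (squared) Euclidean distances between
k-nearest neighbors.  In Gram-matrix form this is a semidefinite program:

    maximize    trace(K)
    subject to  K is positive semidefinite,
                sum_ij K_ij = 0                       (centering),
                K_ii - 2 K_ij + K_jj = ||x_i - x_j||^2  for neighbor edges.

The library builds the SDP data itself (:func:`build_mvu_problem`) and hands
it to whatever solver is registered.  A first-order augmented-Lagrangian
solver (:func:`reference_solver`) ships with the package; register it or any
other callable satisfying the contract before calling :func:`mvu_embed`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.sparse.csgraph import shortest_path

from .dimred import _connected_subset, _fix_signs, EIG_REL_TOL
from .types import Embedding, ExpressionMatrix, ValidationError


class MVUSolverError(RuntimeError):
    """No usable SDP solver, or the solver failed/was infeasible."""


@dataclass
class MVUProblem:
    """SDP data for one MVU instance.

    ``edges`` holds one entry per neighbor-graph edge: (i, j, squared
    Euclidean distance to preserve).  The centering constraint
    ``sum_ij K_ij = 0`` and PSD-ness of K are implicit parts of the contract.
    """

    n: int
    edges: Sequence[tuple]


SDPSolver = Callable[[MVUProblem], np.ndarray]

_registry: dict = {}


def register_sdp_solver(name: str, solver: SDPSolver, default: bool = True) -> None:
    """Register a solver; with ``default=True`` it also becomes the fallback."""
    _registry[name] = solver
    if default:
        _registry["default"] = solver


def registered_solvers() -> tuple:
    return tuple(sorted(n for n in _registry if n != "default"))


def build_mvu_problem(X, k: int) -> MVUProblem:
    """Assemble the MVU constraint list from the k-nearest-neighbor graph."""
    from .dimred import build_neighbor_graph

    G = build_neighbor_graph(X, k, "nearest")
    edges = [(i, j, w * w) for (i, j, w) in sorted(G.edges)]
    return MVUProblem(n=G.n_nodes, edges=edges)


def mvu_embed(X: ExpressionMatrix, d: int, k: int, solver: SDPSolver | str | None = None) -> Embedding:
    """Embed by solving the MVU semidefinite program.

    ``solver`` may be a callable satisfying the contract, the name of a
    registered solver, or None (falls back to the registered default).  A
    disconnected neighbor graph is reduced to its largest connected
    component first; on that component the SDP is bounded.
    """
    if solver is None:
        solver = _registry.get("default")
        if solver is None:
            raise MVUSolverError(
                "no SDP solver registered; register one with "
                "lowdim.mvu.register_sdp_solver (e.g. the built-in reference_solver)"
            )
    elif isinstance(solver, str):
        if solver not in _registry:
            raise MVUSolverError(f"unknown solver {solver!r}; registered: {registered_solvers()}")
        solver = _registry[solver]

    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix.from_array(np.asarray(X, dtype=float))
    Xs, G, dropped = _connected_subset(X, k, "nearest")
    n = Xs.n_samples
    if not 1 <= d <= n - 1:
        raise ValidationError(f"target dimension d={d} outside [1, N-1]=[1, {n - 1}]")
    problem = MVUProblem(n=n, edges=[(i, j, w * w) for (i, j, w) in sorted(G.edges)])
    try:
        K = np.asarray(solver(problem), dtype=float)
    except MVUSolverError:
        raise
    except Exception as exc:  # surface solver diagnostics
        raise MVUSolverError(f"SDP solver failed: {exc}") from exc
    if K.shape != (n, n):
        raise MVUSolverError(f"solver returned shape {K.shape}, expected {(n, n)}")
    K = 0.5 * (K + K.T)
    lam, V = eigh(K)
    lam, V = lam[::-1], V[:, ::-1]
    scale = max(abs(lam).max(), 1e-300)
    if lam[-1] < -1e-6 * scale:
        warnings.warn(f"solver Gram matrix is not PSD (min eigenvalue {lam[-1]:.3g})")
    lam_d = np.where(lam[:d] > EIG_REL_TOL * scale, lam[:d], 0.0)
    coords = _fix_signs(V[:, :d] * np.sqrt(lam_d))
    return Embedding(coords, "MVU", {"d": d, "k": k}, list(Xs.sample_ids), dropped)


# ---------------------------------------------------------------------------
# built-in first-order solver


def _constraint_residuals(K: np.ndarray, problem: MVUProblem) -> np.ndarray:
    c = np.empty(len(problem.edges) + 1)
    for e, (i, j, d2) in enumerate(problem.edges):
        c[e] = K[i, i] - 2.0 * K[i, j] + K[j, j] - d2
    c[-1] = K.sum() / problem.n  # scaled centering constraint
    return c


def _dual_gradient_matrix(coeff: np.ndarray, problem: MVUProblem) -> np.ndarray:
    """Sum of coeff_c * A_c for the linear constraint maps A_c."""
    n = problem.n
    Gm = np.full((n, n), coeff[-1] / n)
    for e, (i, j, _) in enumerate(problem.edges):
        a = coeff[e]
        Gm[i, i] += a
        Gm[j, j] += a
        Gm[i, j] -= a
        Gm[j, i] -= a
    return Gm


def reference_solver(
    problem: MVUProblem,
    max_outer: int = 40,
    tol: float = 1e-9,
    mu0: float = 1.0,
    inner_maxiter: int = 400,
) -> np.ndarray:
    """Augmented-Lagrangian solver for the MVU semidefinite program.

    The PSD variable is factorized as K = V V' (so positive semidefiniteness
    is structural) and each outer iteration minimizes the augmented
    Lagrangian over V with L-BFGS, then updates the multipliers.  Warm-started
    from classical MDS on graph shortest paths, which is already close to the
    unfolded optimum for manifold-like inputs.  Intended for small instances
    (tens to a few hundred samples); convergence is declared when the largest
    relative constraint violation falls below ``tol``.
    """
    n = problem.n
    scale = max((d2 for (_, _, d2) in problem.edges), default=1.0)
    # warm start: MDS on shortest-path distances through the constraint graph
    adj = np.full((n, n), np.inf)
    for i, j, d2 in problem.edges:
        adj[i, j] = adj[j, i] = np.sqrt(d2)
    np.fill_diagonal(adj, 0.0)
    DG = shortest_path(np.ma.masked_array(adj, mask=~np.isfinite(adj)), directed=False)
    B = DG * DG
    B = -0.5 * (B - B.mean(0) - B.mean(1)[:, None] + B.mean())
    lam, U = eigh(B)
    lam = np.clip(lam, 0.0, None)
    V = U * np.sqrt(lam)

    y = np.zeros(len(problem.edges) + 1)
    mu = mu0

    def objective(vflat: np.ndarray):
        Vm = vflat.reshape(n, n)
        K = Vm @ Vm.T
        c = _constraint_residuals(K, problem)
        f = -np.trace(K) + y @ c + 0.5 * mu * (c @ c)
        Gk = -np.eye(n) + _dual_gradient_matrix(y + mu * c, problem)
        grad = 2.0 * Gk @ Vm
        return f, grad.ravel()

    for _ in range(max_outer):
        res = minimize(
            objective,
            V.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": inner_maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        V = res.x.reshape(n, n)
        K = V @ V.T
        c = _constraint_residuals(K, problem)
        if np.abs(c).max() < tol * scale:
            break
        y = y + mu * c
        mu = min(mu * 2.0, 1e8)
    return V @ V.T
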