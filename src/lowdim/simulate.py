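"""Synthetic data generators.

The expression simulator emulates a two-class microarray experiment: genes
are standard normal with a block-diagonal compound-symmetry covariance
(correlation rho inside blocks, zero across), and a chosen number of
differential genes get a constant shift added for the first half of the
samples.  A Swiss-Roll generator provides the classic manifold fixture for
testing nonlinear embeddings, and two helpers implement the noise protocol
(global [0,1] scaling followed by additive Gaussian noise).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix, ValidationError


@dataclass
class SimulationConfig:
    """All expression-generator parameters.

    Defaults are the study conditions: 50 samples, 10,000 genes, within-block
    correlation 0.2 in 50x50 blocks, differential shift +0.6 applied to the
    first half of the samples (class 1).  ``n_diff`` is 0 by default (null
    data); the benchmark sweeps it between 10 and 500.
    """

    n_samples: int = 50
    n_genes: int = 10_000
    rho: float = 0.2
    block_size: int = 50
    n_diff: int = 0
    shift: float = 0.6
    noise_variance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_samples % 2 != 0:
            raise ValidationError("n_samples must be an even integer >= 2 (balanced classes)")
        if self.n_genes % self.block_size != 0:
            raise ValidationError(
                f"n_genes={self.n_genes} must be divisible by block_size={self.block_size}"
            )
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0 <= self.n_diff <= self.n_genes:
            raise ValidationError(f"n_diff must lie in [0, n_genes], got {self.n_diff}")
        if self.noise_variance < 0:
            raise ValidationError("noise variance must be non-negative")


def simulate_expression(cfg: SimulationConfig):
    """Draw one synthetic two-class expression matrix.

    Block correlation is induced by a shared per-block factor:
    ``g = sqrt(rho) * z_block + sqrt(1 - rho) * eps`` has exact N(0,1)
    marginals, correlation rho inside blocks and 0 across.  ``cfg.n_diff``
    genes chosen uniformly at random get ``cfg.shift`` added for the first
    half of the samples (class 1; the second half is class 0).

    Returns
    -------
    (ExpressionMatrix, ndarray)
        The matrix (labels attached) and the sorted differential gene indices.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g, bs = cfg.n_samples, cfg.n_genes, cfg.block_size
    n_blocks = g // bs
    z_block = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, g))
    block_of = np.repeat(np.arange(n_blocks), bs)
    values = np.sqrt(cfg.rho) * z_block[:, block_of] + np.sqrt(1.0 - cfg.rho) * eps
    diff_idx = np.sort(rng.choice(g, size=cfg.n_diff, replace=False))
    half = n // 2
    values[:half, diff_idx] += cfg.shift
    sids = [f"S{i + 1}" for i in range(n)]
    fids = [f"g{j + 1}" for j in range(g)]
    labels = {s: (1 if i < half else 0) for i, s in enumerate(sids)}
    X = ExpressionMatrix(values, sids, fids, labels)
    if cfg.noise_variance > 0:
        X = add_noise(scale_unit_interval(X), cfg.noise_variance, seed=cfg.seed)
    return X, diff_idx


def scale_unit_interval(X: ExpressionMatrix) -> ExpressionMatrix:
    """Affinely map the whole matrix onto [0, 1] (global min-max scaling).

    Scaling is global per matrix, not per feature: it is meant to put whole
    datasets with different means and spreads on a common scale before noise
    of a fixed variance is added.
    """
    lo = X.values.min()
    hi = X.values.max()
    if hi == lo:
        raise ValidationError("cannot scale a constant matrix to [0, 1]")
    return X.with_values((X.values - lo) / (hi - lo))


def add_noise(X: ExpressionMatrix, variance: float, seed: int) -> ExpressionMatrix:
    """Add i.i.d. Gaussian noise with the given variance to every entry.

    Callers are expected to scale to [0, 1] first so that a given variance
    means the same corruption level for every dataset; values outside [0, 1]
    only trigger a warning.  The result is *not* re-scaled (noise is applied
    last).
    """
    if variance < 0:
        raise ValidationError("noise variance must be non-negative")
    if X.values.min() < 0.0 or X.values.max() > 1.0:
        warnings.warn("adding noise to data outside [0, 1]; did you forget scale_unit_interval?")
    if variance == 0:
        return X.with_values(X.values.copy())
    rng = np.random.default_rng(seed)
    return X.with_values(X.values + rng.normal(0.0, np.sqrt(variance), size=X.values.shape))


def swiss_roll(n: int, seed: int):
    """Sample the Swiss-Roll manifold: points (t cos t, h, t sin t).

    The roll parameter t is uniform on [1.5*pi, 4.5*pi] and the height h
    uniform on [0, 21] (conventional ranges).  Returns the 3-D points and the
    latent (t, h) parameters for manifold-recovery checks.
    """
    if n < 10:
        raise ValidationError(f"need at least 10 points, got {n}")
    rng = np.random.default_rng(seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
    h = rng.uniform(0.0, 21.0, size=n)
    points = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    return points, np.column_stack([t, h])
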