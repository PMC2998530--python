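"""Core data containers shared by every module.

Samples are rows everywhere; all indices are 0-based internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for s in ids:
            if s in seen:
                dups.append(s)
            seen.add(s)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of real expression values.

    Parameters
    ----------
    values
        N x D real matrix, rows are samples, columns are genes/features.
    sample_ids
        N unique sample identifiers, aligned with the rows of ``values``.
    feature_ids
        D unique feature identifiers, aligned with the columns.
    labels
        Optional mapping ``sample_id -> class`` with classes in {0, 1}.
        Labels are only consulted by the assessment protocol, never by the
        embeddings themselves.
    """

    values: np.ndarray
    sample_ids: Sequence[str]
    feature_ids: Sequence[str]
    labels: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D matrix")
        n, d = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if d < 1:
            raise ValidationError("need at least 1 feature")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-finite expression value at sample row {bad[0]}, "
                f"feature column {bad[1]}; impute or drop explicitly before loading"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match number of rows")
        if len(self.feature_ids) != d:
            raise ValidationError("feature_ids length does not match number of columns")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_ids, "feature ids")
        if self.labels is not None:
            unknown = set(self.labels) - set(self.sample_ids)
            if unknown:
                raise ValidationError(f"labels given for unknown sample ids: {sorted(unknown)}")

    @classmethod
    def from_array(cls, values: np.ndarray, labels: Sequence[int] | None = None) -> "ExpressionMatrix":
        """Wrap a bare array, generating positional identifiers."""
        values = np.asarray(values, dtype=float)
        n, d = values.shape
        sids = [f"S{i + 1}" for i in range(n)]
        fids = [f"g{j + 1}" for j in range(d)]
        lab = None if labels is None else {s: int(c) for s, c in zip(sids, labels)}
        return cls(values, sids, fids, lab)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_vector(self) -> np.ndarray:
        """Class labels aligned with the sample rows (requires complete labels)."""
        if self.labels is None:
            raise ValidationError("expression matrix carries no class labels")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"samples without a class label: {missing}")
        return np.array([self.labels[s] for s in self.sample_ids])

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Copy with replaced values (ids and labels preserved)."""
        return ExpressionMatrix(values, list(self.sample_ids), list(self.feature_ids), self.labels)

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        ids = [self.sample_ids[i] for i in idx]
        lab = None
        if self.labels is not None:
            lab = {s: self.labels[s] for s in ids if s in self.labels}
        return ExpressionMatrix(self.values[list(idx)], ids, list(self.feature_ids), lab)


@dataclass
class Embedding:
    """A low-dimensional representation of an expression matrix."""

    coords: np.ndarray
    method: str
    params: Mapping[str, object]
    sample_ids: Sequence[str]
    dropped_ids: tuple = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("embedding coordinates must form a 2-D matrix")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding coordinates must be finite")
        if len(self.sample_ids) != self.coords.shape[0]:
            raise ValidationError("sample_ids length does not match embedding rows")
        d = self.params.get("d")
        if d is not None and int(d) != self.coords.shape[1]:
            raise ValidationError("declared target dimension does not match coordinates")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Weighted undirected neighbor graph over samples.

    Edge weights are Euclidean distances. ``mask`` is the symmetric boolean
    adjacency after edge-union symmetrization; ``dist`` holds all pairwise
    distances (so zero-weight edges between duplicate samples stay edges).
    """

    n_nodes: int
    k: int
    mode: str
    mask: np.ndarray
    dist: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in ("nearest", "nearest_farthest"):
            raise ValidationError(f"unknown neighbor mode {self.mode!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.dist = np.asarray(self.dist, dtype=float)
        if self.mask.shape != (self.n_nodes, self.n_nodes):
            raise ValidationError("adjacency mask has wrong shape")
        if not (self.mask == self.mask.T).all():
            raise ValidationError("neighbor graph must be undirected (symmetric)")
        if self.mask.diagonal().any():
            raise ValidationError("neighbor graph must not contain self-loops")
        if (self.dist < 0).any():
            raise ValidationError("edge weights must be non-negative")

    @property
    def edges(self) -> set:
        """Set of (i, j, weight) with i < j."""
        out = set()
        ii, jj = np.nonzero(np.triu(self.mask, 1))
        for i, j in zip(ii, jj):
            out.add((int(i), int(j), float(self.dist[i, j])))
        return out

    def masked_adjacency(self) -> np.ma.MaskedArray:
        """Dense masked adjacency suitable for scipy.sparse.csgraph routines."""
        return np.ma.masked_array(self.dist, mask=~self.mask)


@dataclass
class KernelParams:
    """Gaussian kernel width and diffusion time.

    The kernel is K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma^2) — note the
    denominator sigma^2 (not 2 sigma^2).
    """

    sigma: float = 1.0
    t: int = 1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError(f"kernel width sigma must be positive, got {self.sigma}")
        self.t = int(self.t)
        if self.t < 1:
            raise ValidationError(f"diffusion time t must be >= 1, got {self.t}")
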