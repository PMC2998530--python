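"""Cluster-validity scoring and paired hypothesis testing.

Two tools used to compare embeddings: the Davies-Bouldin index (lower is
better; it averages, over clusters, the worst-case ratio of summed
within-cluster scatter to between-center distance) and the exact Wilcoxon
signed-rank test for paired per-dataset scores.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .types import ValidationError


@dataclass
class ClusterScore:
    """Davies-Bouldin score plus the per-cluster worst-case ratios."""

    db_index: float
    per_cluster_worst: np.ndarray
    centers: np.ndarray
    dims_evaluated: int


@dataclass
class PairedTestResult:
    n_pairs: int
    statistic: float
    p_value: float
    alternative: str


def davis_bouldin(coords: np.ndarray, labels) -> ClusterScore:
    """Davies-Bouldin cluster-validity index with Euclidean geometry.

    For clusters C_i with centers mu_i, within-cluster scatter
    d_i = mean ||x - mu_i|| and pairwise ratio
    R_ij = (d_i + d_j) / ||mu_i - mu_j||, the index is the mean over clusters
    of max_j R_ij.  Singleton clusters are legal (d_i = 0); two clusters with
    identical centers are an error because R_ij is undefined.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValidationError("coordinates must form a 2-D matrix")
    if not np.isfinite(coords).all():
        raise ValidationError("coordinates must be finite")
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ValidationError("labels length does not match number of samples")
    classes = np.unique(labels)
    m = classes.size
    if m < 2:
        raise ValidationError(f"need at least 2 clusters, got {m}")
    centers = np.stack([coords[labels == c].mean(axis=0) for c in classes])
    scatter = np.array(
        [np.linalg.norm(coords[labels == c] - centers[i], axis=1).mean() for i, c in enumerate(classes)]
    )
    worst = np.empty(m)
    for i in range(m):
        rij = []
        for j in range(m):
            if i == j:
                continue
            sep = np.linalg.norm(centers[i] - centers[j])
            if sep == 0.0:
                raise ValidationError(
                    f"clusters {classes[i]!r} and {classes[j]!r} have identical centers"
                )
            rij.append((scatter[i] + scatter[j]) / sep)
        worst[i] = max(rij)
    return ClusterScore(
        db_index=float(worst.mean()),
        per_cluster_worst=worst,
        centers=centers,
        dims_evaluated=coords.shape[1],
    )


def _signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of subsets of (doubled, integer) ranks achieving each sum.

    Equivalent to enumerating all 2^n sign assignments; the distribution of
    the positive-rank sum under the null is the subset-sum profile.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(a, b, alternative: str = "two_sided") -> PairedTestResult:
    """Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped before ranking and ties receive midranks.
    For n <= 25 retained pairs the p-value comes from the exact null
    distribution (all 2^n sign assignments of the observed ranks); above
    that, a normal approximation with tie correction and continuity
    correction is used.  ``alternative`` is one of ``two_sided``, ``greater``
    (median of a-b > 0) or ``less``.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D sequences")
    diff = a - b
    diff = diff[diff != 0.0]
    n = diff.size
    if n == 0:
        raise ValidationError("all differences are zero; the test is undefined")
    ranks = rankdata(np.abs(diff))  # midranks for ties
    w_pos = float(ranks[diff > 0].sum())
    total = float(ranks.sum())  # == n(n+1)/2

    if n <= 25:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_null_counts(ranks2)
        denom = counts.sum()  # 2^n
        w2 = int(round(2.0 * w_pos))
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
    else:
        mean = total / 2.0
        # variance of the rank sum with midrank ties: sum(ranks^2)/4
        sd = np.sqrt(np.sum(ranks**2) / 4.0)
        p_ge = norm.sf((w_pos - 0.5 - mean) / sd)
        p_le = norm.cdf((w_pos + 0.5 - mean) / sd)

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return PairedTestResult(n_pairs=n, statistic=w_pos, p_value=float(p), alternative=alternative)
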