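"""Classifier contract and cross-validation scoring.

The assessment protocol scores embeddings with a Gaussian-kernel Support
Vector Machine.  The classifier is a narrow contract (train/predict with
explicit C and gamma) so the benchmark stays agnostic of the backing
implementation; :class:`SVMClassifier` backs it with scikit-learn's SVC.
"""
from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np
from sklearn.svm import SVC

from .types import ValidationError

#: default hyperparameter grids for the loo-cv model selection
DEFAULT_CS = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMAS = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


class ClassifierContract(Protocol):
    def train(self, points: np.ndarray, labels: np.ndarray, C: float, gamma: float): ...

    def predict(self, predictor, points: np.ndarray) -> np.ndarray: ...


class SVMClassifier:
    """Gaussian-kernel SVM satisfying the classifier contract (deterministic)."""

    def train(self, points, labels, C, gamma):
        model = SVC(C=C, gamma=gamma, kernel="rbf")
        model.fit(points, labels)
        return model

    def predict(self, predictor, points):
        return predictor.predict(points)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("classification requires both classes to be present")
    return labels


def loo_cv_accuracy(coords, labels, clf: ClassifierContract, C: float, gamma: float) -> float:
    """Leave-one-out cross-validation accuracy at fixed hyperparameters.

    The dataset is split N times; one sample is held out for testing and the
    classifier is retrained on the remainder.  Returns the fraction of
    held-out samples predicted correctly.
    """
    coords = np.asarray(coords, dtype=float)
    labels = _check_labels(labels)
    n = coords.shape[0]
    if n < 3:
        raise ValidationError(f"need at least 3 samples for loo-cv, got {n}")
    hits = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if np.unique(labels[tr]).size < 2:
            continue  # degenerate fold: held-out class is a singleton class
        model = clf.train(coords[tr], labels[tr], C, gamma)
        if clf.predict(model, coords[i : i + 1])[0] == labels[i]:
            hits += 1
    return hits / n


def adaptive_gammas(coords, base: Sequence[float] = (0.1, 1.0, 10.0)) -> tuple:
    """Gamma grid centered on the median squared pairwise distance.

    Embedding coordinate scales differ by orders of magnitude between methods
    (eigenvalue-scaled PCA/Isomap axes versus unit-variance LLE output), so a
    fixed gamma grid systematically underfits some of them.  The median
    heuristic re-centers the grid per embedding; it is equivalent to applying
    a fixed grid to globally rescaled coordinates, so relative geometry is
    untouched.
    """
    coords = np.asarray(coords, dtype=float)
    d2 = ((coords[:, None] - coords[None]) ** 2).sum(-1)
    m = np.median(d2[np.triu_indices_from(d2, 1)])
    if not m > 0:
        m = 1.0
    return tuple(b / m for b in base)


def grid_loo_accuracy(
    coords,
    labels,
    clf: ClassifierContract,
    Cs: Sequence[float] = DEFAULT_CS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
):
    """Best loo-cv accuracy over a (C, gamma) grid.

    Ties are broken toward the smaller C, then the smaller gamma, so the
    selection is a total order and repeated runs agree exactly.

    Returns
    -------
    (accuracy, C, gamma)
    """
    best = None
    for C in sorted(Cs):
        for gamma in sorted(gammas):
            acc = loo_cv_accuracy(coords, labels, clf, C, gamma)
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    return best
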