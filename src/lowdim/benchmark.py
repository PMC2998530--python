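"""The three-part assessment protocol.

1. *Parameter selection*: every candidate (dimension, neighbor/kernel
   parameter) embeds the complete dataset once and is scored by
   leave-one-out SVM accuracy; ties go to the lowest dimension, then the
   lowest neighbor count, then the smallest kernel width.
2. *Randomization classification*: one hundred stratified 2/3-train /
   1/3-test splits; the SVM's (C, gamma) is re-selected on each training set
   by loo-cv grid search; the median test accuracy summarizes the method.
3. *Cluster validation*: the Davies-Bouldin index of the class labels in the
   embedding, at fixed target dimensions 2, 3, 5 and 10.

A noise sweep and a simulation study compose these stages over corrupted
and synthetic datasets.

Note the protocol's deliberate transductive bent: dimension reduction is
applied to the complete dataset *before* any cross-validation split, so
held-out samples have already influenced the embedding geometry.  Scores are
comparable across methods but optimistically biased in absolute terms.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    DEFAULT_CS,
    DEFAULT_GAMMAS,
    SVMClassifier,
    adaptive_gammas,
    grid_loo_accuracy,
    loo_cv_accuracy,
)
from .dimred import METHOD_AXES, embed
from .simulate import SimulationConfig, add_noise, scale_unit_interval, simulate_expression
from .types import ExpressionMatrix, ValidationError
from .validate import davis_bouldin

log = logging.getLogger("lowdim.benchmark")


def derive_seed(*keys: int) -> int:
    """Reproducible sub-seed from a base seed plus counter keys (< 2^31)."""
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ParamGrid:
    """Search ranges for the embedding parameters.

    Defaults cover dimensions 2..15, neighbor counts 4..16 and eight
    log-spaced Gaussian kernel widths between 1e-1 and 5e5.
    """

    dims: Sequence[int] = tuple(range(2, 16))
    neighbors: Sequence[int] = tuple(range(4, 17))
    sigmas: Sequence[float] = (0.1, 1.0, 10.0, 100.0, 1e3, 1e4, 1e5, 5e5)

    def __post_init__(self) -> None:
        if not (len(self.dims) and len(self.neighbors) and len(self.sigmas)):
            raise ValidationError("parameter grid axes must be non-empty")


@dataclass
class RandomizationResult:
    accuracies: np.ndarray
    median_accuracy: float


@dataclass
class BenchmarkResult:
    """Everything the protocol records for one method on one dataset."""

    method: str
    best_params: Mapping[str, object]
    loo_accuracy: float
    randomization_accuracies: np.ndarray
    median_accuracy: float
    db_by_dim: Mapping[int, float]
    noise_curve: Mapping[float, tuple] | None = None
    selection_table: pd.DataFrame | None = None


def _axes_for(method: str, grid: ParamGrid):
    needs = METHOD_AXES[method.upper()]
    ks = list(grid.neighbors) if "k" in needs else [None]
    sigmas = list(grid.sigmas) if "sigma" in needs else [None]
    ignored = []
    if "k" not in needs and list(grid.neighbors):
        ignored.append("neighbors")
    if "sigma" not in needs and list(grid.sigmas):
        ignored.append("sigmas")
    if ignored:
        log.info("method %s ignores grid axes: %s", method, ", ".join(ignored))
    if method.upper() == "IM_MOD":
        even = [k for k in ks if k % 2 == 0]
        if len(even) < len(ks):
            log.info("IM_MOD: skipping odd neighbor counts %s", [k for k in ks if k % 2])
        ks = even
        if not ks:
            raise ValidationError("IM_MOD requires at least one even neighbor count in the grid")
    return ks, sigmas


def select_parameters(
    X: ExpressionMatrix,
    method: str,
    grid: ParamGrid,
    clf=None,
    Cs: Sequence[float] = DEFAULT_CS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    solver=None,
):
    """Pick embedding parameters by leave-one-out SVM accuracy.

    Class labels are used only to score candidate parameter sets; every
    candidate embedding itself is computed without labels.  Equal accuracies
    are resolved toward the lowest target dimension, then the lowest
    neighbor count, then the smallest kernel width (simplest representation
    wins).

    Returns
    -------
    (best, table)
        ``best`` maps parameter names to the selected values (plus the
        selected SVM hyperparameters and achieved accuracy); ``table`` is a
        tidy DataFrame with one row per evaluated grid point.
    """
    clf = clf or SVMClassifier()
    labels = X.label_vector()
    method = method.upper()
    ks, sigmas = _axes_for(method, grid)
    rows = []
    best = None  # (acc, d, k, sigma, C, gamma)
    for d, k, sigma in product(sorted(grid.dims), sorted(ks, key=lambda v: (v is None, v)), sorted(sigmas, key=lambda v: (v is None, v))):
        try:
            emb = embed(X, method, d, k=k, sigma=sigma, solver=solver)
        except Exception as exc:
            log.warning("embedding %s failed at d=%s k=%s sigma=%s: %s", method, d, k, sigma, exc)
            rows.append({"method": method, "d": d, "k": k, "sigma": sigma, "accuracy": np.nan})
            continue
        if emb.dropped_ids:
            keep = [sid in set(emb.sample_ids) for sid in X.sample_ids]
            lab = labels[np.asarray(keep)]
        else:
            lab = labels
        acc, C, gamma = grid_loo_accuracy(emb.coords, lab, clf, Cs, gammas)
        rows.append(
            {"method": method, "d": d, "k": k, "sigma": sigma, "accuracy": acc, "C": C, "gamma": gamma}
        )
        key = (-acc, d, k if k is not None else -1, sigma if sigma is not None else -1.0)
        if best is None or key < best[0]:
            best = (key, {"d": d, "k": k, "sigma": sigma, "C": C, "gamma": gamma, "loo_accuracy": acc})
        log.debug("%s d=%s k=%s sigma=%s -> loo %.4f", method, d, k, sigma, acc)
    if best is None or not np.isfinite(best[1]["loo_accuracy"]):
        raise ValidationError(f"no grid point could be evaluated for method {method}")
    table = pd.DataFrame(rows)
    log.info("%s selected %s", method, best[1])
    return best[1], table


def stratified_split(labels: np.ndarray, rng: np.random.Generator):
    """Random 2/3-train / 1/3-test split preserving class proportions.

    Per class the train share is floor(2/3 * n_class) with the remainder
    going to the training side when rounding allows (i.e. ceil keeps at
    least one test sample).
    """
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 3:
            raise ValidationError(f"class {c!r} has fewer than 3 members; cannot stratify")
        perm = rng.permutation(members)
        n_train = int(np.floor(members.size * 2 / 3))
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(train_idx), np.sort(test_idx)


def randomization_classification(
    coords,
    labels,
    clf=None,
    n_rounds: int = 100,
    seed: int = 0,
    Cs: Sequence[float] = DEFAULT_CS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
) -> RandomizationResult:
    """Median SVM accuracy over repeated stratified train/test splits.

    Each round draws a fresh stratified 2/3-train split (round r uses the
    seed ``derive_seed(seed, r)`` so rounds are independently reproducible),
    selects (C, gamma) by loo-cv grid search on the training portion only,
    and records the test accuracy.
    """
    clf = clf or SVMClassifier()
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    accs = np.empty(n_rounds)
    for r in range(n_rounds):
        rng = np.random.default_rng(derive_seed(seed, r))
        tr, te = stratified_split(labels, rng)
        _, C, gamma = grid_loo_accuracy(coords[tr], labels[tr], clf, Cs, gammas)
        model = clf.train(coords[tr], labels[tr], C, gamma)
        accs[r] = float(np.mean(clf.predict(model, coords[te]) == labels[te]))
    return RandomizationResult(accuracies=accs, median_accuracy=float(np.median(accs)))


def run_benchmark(
    X: ExpressionMatrix,
    methods: Sequence[str],
    grid: ParamGrid | None = None,
    clf=None,
    db_dims: Sequence[int] = (2, 3, 5, 10),
    seed: int = 0,
    n_rounds: int = 100,
    Cs: Sequence[float] = DEFAULT_CS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    solver=None,
) -> list:
    """Run parameter selection, randomization and cluster validation per method.

    A method that fails outright is reported (warning) and skipped rather
    than aborting the whole run.  Results do not depend on the order in
    which methods are listed.
    """
    grid = grid or ParamGrid()
    clf = clf or SVMClassifier()
    labels = X.label_vector()
    results = []
    for method in methods:
        method = method.upper()
        try:
            best, table = select_parameters(X, method, grid, clf, Cs, gammas, solver=solver)
            emb = embed(X, method, best["d"], k=best["k"], sigma=best["sigma"], solver=solver)
            lab = _aligned_labels(X, emb, labels)
            rand = randomization_classification(
                emb.coords, lab, clf, n_rounds=n_rounds, seed=derive_seed(seed, _method_code(method)), Cs=Cs, gammas=gammas
            )
            db_by_dim = {}
            for dd in db_dims:
                if dd > X.n_samples - 2:
                    continue
                emb_d = embed(X, method, dd, k=best["k"], sigma=best["sigma"], solver=solver)
                db_by_dim[dd] = davis_bouldin(emb_d.coords, _aligned_labels(X, emb_d, labels)).db_index
            results.append(
                BenchmarkResult(
                    method=method,
                    best_params={k: v for k, v in best.items() if k in ("d", "k", "sigma", "C", "gamma")},
                    loo_accuracy=best["loo_accuracy"],
                    randomization_accuracies=rand.accuracies,
                    median_accuracy=rand.median_accuracy,
                    db_by_dim=db_by_dim,
                    selection_table=table,
                )
            )
        except Exception as exc:
            warnings.warn(f"method {method} failed and was skipped: {exc}")
    return results


def _method_code(method: str) -> int:
    """Stable per-method seed offset, independent of the method list order."""
    from .dimred import METHODS

    return METHODS.index(method.upper())


def _aligned_labels(X: ExpressionMatrix, emb, labels: np.ndarray) -> np.ndarray:
    if not emb.dropped_ids:
        return labels
    keep = np.asarray([sid in set(emb.sample_ids) for sid in X.sample_ids])
    return labels[keep]


def noise_evaluation(
    X: ExpressionMatrix,
    variances: Sequence[float],
    methods: Sequence[str],
    grid: ParamGrid | None = None,
    clf=None,
    seed: int = 0,
    db_dims: Sequence[int] = (2, 3, 5, 10),
    n_rounds: int = 100,
    Cs: Sequence[float] = DEFAULT_CS,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
) -> pd.DataFrame:
    """Re-run the benchmark on noise-corrupted copies of the dataset.

    The matrix is scaled onto [0, 1] once, then for each variance i.i.d.
    Gaussian noise is added (variance 0 reproduces the scaled original) and
    the full benchmark runs with the same base seed.  Returns one record per
    (method, variance) with the median randomization accuracy and the
    2-D Davies-Bouldin score.
    """
    Xs = scale_unit_interval(X)
    rows = []
    for v, variance in enumerate(variances):
        Xn = add_noise(Xs, variance, seed=derive_seed(seed, 1000 + v))
        for res in run_benchmark(
            Xn, methods, grid, clf, db_dims=db_dims, seed=seed, n_rounds=n_rounds, Cs=Cs, gammas=gammas
        ):
            rows.append(
                {
                    "method": res.method,
                    "variance": variance,
                    "median_accuracy": res.median_accuracy,
                    "db_index_dim2": res.db_by_dim.get(2, np.nan),
                }
            )
    return pd.DataFrame(rows)


def simulation_study(
    diff_counts: Sequence[int],
    n_replicates: int,
    methods: Sequence[str] = ("PCA", "LLE", "IM"),
    d: int = 2,
    clf=None,
    seed: int = 0,
    k_grid: Sequence[int] = (4, 8, 12, 16),
    config: SimulationConfig | None = None,
    Cs: Sequence[float] = (1.0, 10.0, 100.0),
    gammas: Sequence[float] | None = None,
    noise_variance: float = 0.0,
) -> pd.DataFrame:
    """Sweep the number of differential genes over replicated synthetic data.

    For every (count, replicate) a fresh dataset is simulated; each method
    embeds it at the fixed target dimension ``d`` (neighbor-based methods
    pick k from ``k_grid`` by loo-cv) and is scored by leave-one-out SVM
    accuracy with grid-searched hyperparameters.  ``gammas=None`` uses the
    median-heuristic adaptive grid per embedding (see
    :func:`lowdim.classify.adaptive_gammas`).  Returns a tidy table with one
    row per (count, replicate, method).
    """
    clf = clf or SVMClassifier()
    base = config or SimulationConfig()
    rows = []
    for count in diff_counts:
        for rep in range(n_replicates):
            cfg = SimulationConfig(
                n_samples=base.n_samples,
                n_genes=base.n_genes,
                rho=base.rho,
                block_size=base.block_size,
                n_diff=count,
                shift=base.shift,
                noise_variance=noise_variance,
                seed=derive_seed(seed, count, rep),
            )
            X, _ = simulate_expression(cfg)
            labels = X.label_vector()
            for method in methods:
                method = method.upper()
                needs_k = "k" in METHOD_AXES[method]
                best = None  # (acc, k, C, gamma)
                for k in sorted(k_grid) if needs_k else [None]:
                    emb = embed(X, method, d, k=k, sigma=None)
                    gg = adaptive_gammas(emb.coords) if gammas is None else gammas
                    acc, C, gamma = grid_loo_accuracy(emb.coords, labels, clf, Cs, gg)
                    if best is None or acc > best[0]:
                        best = (acc, k, C, gamma)
                rows.append(
                    {
                        "n_diff": count,
                        "replicate": rep,
                        "method": method,
                        "k": best[1],
                        "C": best[2],
                        "gamma": best[3],
                        "accuracy": best[0],
                    }
                )
        log.info("simulation study: finished n_diff=%d", count)
    return pd.DataFrame(rows)


def summarize_simulation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy and central 95% quantile band per (method, count)."""
    return (
        table.groupby(["method", "n_diff"])["accuracy"]
        .agg(
            mean="mean",
            q_low=lambda s: s.quantile(0.025),
            q_high=lambda s: s.quantile(0.975),
            n="count",
        )
        .reset_index()
    )


def pca_catchup_count(summary: pd.DataFrame, margin: float = 0.02) -> float:
    """Smallest differential-gene count at which PCA's mean accuracy comes
    within ``margin`` of the better of LLE and Isomap.

    Returns infinity if PCA never catches up within the swept range.
    """
    pivot = summary.pivot(index="n_diff", columns="method", values="mean").sort_index()
    nonlinear = [m for m in ("LLE", "IM") if m in pivot.columns]
    if "PCA" not in pivot.columns or not nonlinear:
        raise ValidationError("summary must contain PCA and at least one of LLE/IM")
    for count, row in pivot.iterrows():
        if row["PCA"] >= max(row[m] for m in nonlinear) - margin:
            return float(count)
    return float("inf")
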