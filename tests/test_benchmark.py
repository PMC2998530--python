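"""Cross-validation scoring, parameter selection and the benchmark stages."""
import numpy as np
import pandas as pd
import pytest

from lowdim import ExpressionMatrix, ValidationError
from lowdim.benchmark import (
    ParamGrid,
    derive_seed,
    noise_evaluation,
    pca_catchup_count,
    randomization_classification,
    run_benchmark,
    select_parameters,
    simulation_study,
    stratified_split,
    summarize_simulation,
)
from lowdim.classify import SVMClassifier, adaptive_gammas, grid_loo_accuracy, loo_cv_accuracy
from lowdim.simulate import SimulationConfig, scale_unit_interval, simulate_expression


def two_blobs(rng, n_per=10, sep=20.0, d=2):
    pts = np.vstack(
        [rng.normal(size=(n_per, d)), rng.normal(size=(n_per, d)) + sep]
    )
    labels = np.repeat([0, 1], n_per)
    return pts, labels


SMALL_GRID = dict(Cs=(1.0, 100.0), gammas=(1e-2, 1.0))


class TestLooCV:
    def test_separable_data_scores_one(self, rng):
        pts, labels = two_blobs(rng)
        acc = loo_cv_accuracy(pts, labels, SVMClassifier(), C=10.0, gamma=0.01)
        assert acc == 1.0

    def test_label_independent_coords_score_near_chance(self):
        clf = SVMClassifier()
        accs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            pts = r.normal(size=(60, 2))
            labels = np.repeat([0, 1], 30)
            accs.append(loo_cv_accuracy(pts, labels, clf, C=1.0, gamma=0.5))
        assert 0.35 < np.mean(accs) < 0.65

    def test_equals_literal_protocol_oracle(self, rng):
        pts = rng.normal(size=(6, 2))
        labels = np.array([0, 1, 0, 1, 0, 1])
        clf = SVMClassifier()
        acc = loo_cv_accuracy(pts, labels, clf, C=1.0, gamma=0.3)
        # oracle: hand loop that retrains N times and counts hits
        hits = 0
        for i in range(6):
            tr = [j for j in range(6) if j != i]
            model = clf.train(pts[tr], labels[tr], 1.0, 0.3)
            hits += int(clf.predict(model, pts[i : i + 1])[0] == labels[i])
        assert acc == hits / 6

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            loo_cv_accuracy(rng.normal(size=(5, 2)), np.zeros(5), SVMClassifier(), 1.0, 1.0)

    def test_grid_tie_break_prefers_smaller_hyperparameters(self, rng):
        pts, labels = two_blobs(rng)  # everything scores 1.0
        acc, C, gamma = grid_loo_accuracy(pts, labels, SVMClassifier(), (1.0, 10.0), (0.01, 0.1))
        assert acc == 1.0 and C == 1.0 and gamma == 0.01

    def test_adaptive_gammas_track_coordinate_scale(self, rng):
        pts = rng.normal(size=(20, 2))
        g1 = adaptive_gammas(pts)
        g2 = adaptive_gammas(pts * 100.0)
        assert np.allclose(np.array(g2) * 100.0**2, g1)


class TestSelectParameters:
    def test_singleton_grid_is_returned(self, rng):
        pts, labels = two_blobs(rng, n_per=8, d=4)
        X = ExpressionMatrix.from_array(pts, labels=labels)
        grid = ParamGrid(dims=(2,), neighbors=(4,), sigmas=(1.0,))
        best, table = select_parameters(X, "LLE", grid, **SMALL_GRID)
        assert best["d"] == 2 and best["k"] == 4
        assert len(table) == 1

    def test_accuracy_ties_resolve_to_lowest_dimension(self, rng):
        pts, labels = two_blobs(rng, n_per=8, d=6)  # separable at any d
        X = ExpressionMatrix.from_array(pts, labels=labels)
        best, table = select_parameters(X, "PCA", ParamGrid(dims=(3, 5), neighbors=(4,), sigmas=(1.0,)), **SMALL_GRID)
        assert table["accuracy"].nunique() == 1  # genuine tie
        assert best["d"] == 3

    def test_matches_exhaustive_re_evaluation(self):
        X, _ = simulate_expression(
            SimulationConfig(n_samples=30, n_genes=300, block_size=50, n_diff=200, seed=4)
        )
        grid = ParamGrid(dims=(2, 3), neighbors=(8, 12), sigmas=(1.0,))
        clf = SVMClassifier()
        best, table = select_parameters(X, "LLE", grid, clf, **SMALL_GRID)
        # oracle: independent exhaustive loop over the same grid
        from lowdim.dimred import lle_embed

        labels = X.label_vector()
        results = {}
        for d in (2, 3):
            for k in (8, 12):
                emb = lle_embed(X, d, k)
                results[(d, k)] = grid_loo_accuracy(emb.coords, labels, clf, **SMALL_GRID)[0]
        expected = max(sorted(results), key=lambda key: (results[key], -key[0], -key[1]))
        assert (best["d"], best["k"]) == expected
        assert best["loo_accuracy"] == results[expected]


class TestRandomization:
    def test_stratified_split_counts(self):
        labels = np.repeat([0, 1], 15)
        rng = np.random.default_rng(0)
        tr, te = stratified_split(labels, rng)
        assert len(tr) == 20 and len(te) == 10
        assert (labels[tr] == 0).sum() == 10 and (labels[tr] == 1).sum() == 10

    def test_stratified_split_unbalanced_floor(self):
        labels = np.array([0] * 12 + [1] * 18)
        tr, te = stratified_split(labels, np.random.default_rng(1))
        assert (np.asarray(labels)[tr] == 0).sum() == 8
        assert (np.asarray(labels)[tr] == 1).sum() == 12

    def test_separable_data_has_median_one(self, rng):
        pts, labels = two_blobs(rng, n_per=9)
        res = randomization_classification(pts, labels, n_rounds=10, seed=3, **SMALL_GRID)
        assert res.median_accuracy == 1.0
        assert res.accuracies.shape == (10,)
        assert np.all((0.0 <= res.accuracies) & (res.accuracies <= 1.0))
        assert res.median_accuracy == float(np.median(res.accuracies))

    def test_random_labels_score_near_chance(self):
        r = np.random.default_rng(5)
        pts = r.normal(size=(60, 2))
        labels = np.repeat([0, 1], 30)
        res = randomization_classification(pts, labels, n_rounds=10, seed=7, **SMALL_GRID)
        assert 0.35 <= res.median_accuracy <= 0.65

    def test_rounds_are_reproducible(self, rng):
        pts, labels = two_blobs(rng, n_per=6)
        r1 = randomization_classification(pts, labels, n_rounds=5, seed=11, **SMALL_GRID)
        r2 = randomization_classification(pts, labels, n_rounds=5, seed=11, **SMALL_GRID)
        assert np.array_equal(r1.accuracies, r2.accuracies)


@pytest.fixture(scope="module")
def separable_expression():
    rng = np.random.default_rng(8)
    pts = np.vstack([rng.normal(size=(10, 20)), rng.normal(size=(10, 20)) + 6.0])
    return ExpressionMatrix.from_array(pts, labels=np.repeat([0, 1], 10))


class TestRunBenchmark:
    GRID = ParamGrid(dims=(2,), neighbors=(4,), sigmas=(10.0,))

    def test_separable_fixture_scores_well(self, separable_expression):
        res = run_benchmark(
            separable_expression, ["PCA"], self.GRID, seed=1, n_rounds=6, **SMALL_GRID
        )[0]
        assert res.median_accuracy == 1.0
        assert res.db_by_dim[2] < 1.0
        assert set(res.db_by_dim) == {2, 3, 5, 10}

    def test_results_invariant_to_method_order(self, separable_expression):
        kw = dict(grid=self.GRID, seed=2, n_rounds=4, **SMALL_GRID)
        r1 = run_benchmark(separable_expression, ["PCA", "KPCA"], **kw)
        r2 = run_benchmark(separable_expression, ["KPCA", "PCA"], **kw)
        by1 = {r.method: r for r in r1}
        by2 = {r.method: r for r in r2}
        assert by1.keys() == by2.keys()
        for m in by1:
            assert np.array_equal(by1[m].randomization_accuracies, by2[m].randomization_accuracies)
            assert by1[m].db_by_dim == by2[m].db_by_dim

    def test_composition_equals_manual_stages(self, separable_expression):
        from lowdim.benchmark import _method_code
        from lowdim.dimred import pca_embed
        from lowdim.validate import davis_bouldin

        X = separable_expression
        res = run_benchmark(X, ["PCA"], self.GRID, seed=5, n_rounds=4, **SMALL_GRID)[0]
        clf = SVMClassifier()
        best, _ = select_parameters(X, "PCA", self.GRID, clf, **SMALL_GRID)
        emb = pca_embed(X, best["d"])
        rand = randomization_classification(
            emb.coords, X.label_vector(), clf, n_rounds=4,
            seed=derive_seed(5, _method_code("PCA")), **SMALL_GRID,
        )
        assert res.loo_accuracy == best["loo_accuracy"]
        assert np.array_equal(res.randomization_accuracies, rand.accuracies)
        assert res.db_by_dim[2] == davis_bouldin(pca_embed(X, 2).coords, X.label_vector()).db_index

    def test_failing_method_is_skipped_not_fatal(self, separable_expression):
        grid = ParamGrid(dims=(2,), neighbors=(3,), sigmas=(1.0,))  # odd k: IM_MOD cannot run
        with pytest.warns(UserWarning, match="skipped"):
            res = run_benchmark(separable_expression, ["IM_MOD", "PCA"], grid, seed=1, n_rounds=4, **SMALL_GRID)
        assert [r.method for r in res] == ["PCA"]


class TestNoiseEvaluation:
    def test_zero_variance_matches_noise_free_run(self, separable_expression):
        grid = ParamGrid(dims=(2,), neighbors=(4,), sigmas=(1.0,))
        table = noise_evaluation(
            separable_expression, [0.0, 0.3], ["PCA"], grid, seed=9, n_rounds=4, **SMALL_GRID
        )
        assert len(table) == 2  # one record per (method, variance)
        ref = run_benchmark(
            scale_unit_interval(separable_expression), ["PCA"], grid, seed=9, n_rounds=4, **SMALL_GRID
        )[0]
        row0 = table[table.variance == 0.0].iloc[0]
        assert row0.median_accuracy == ref.median_accuracy
        assert row0.db_index_dim2 == ref.db_by_dim[2]


class TestSimulationStudy:
    def test_identical_seed_gives_identical_table(self):
        cfg = SimulationConfig(n_samples=20, n_genes=200, block_size=50)
        kw = dict(methods=("PCA",), d=2, seed=13, config=cfg, k_grid=(4,))
        t1 = simulation_study([50], 2, **kw)
        t2 = simulation_study([50], 2, **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_strong_signal_is_learnable(self):
        table = simulation_study([500], 2, seed=3, k_grid=(8, 16))
        means = table.groupby("method")["accuracy"].mean()
        assert (means > 0.55).all()  # well above the 0.5 chance rate

    def test_embedding_never_uses_labels(self):
        # shuffling labels must not change the unsupervised coordinates
        from lowdim.dimred import lle_embed

        X, _ = simulate_expression(SimulationConfig(n_samples=20, n_genes=200, block_size=50, n_diff=50, seed=2))
        emb1 = lle_embed(X, 2, 6).coords
        shuffled = dict(zip(X.sample_ids, np.random.default_rng(0).permutation(X.label_vector())))
        X2 = ExpressionMatrix(X.values, list(X.sample_ids), list(X.feature_ids), shuffled)
        emb2 = lle_embed(X2, 2, 6).coords
        assert np.array_equal(emb1, emb2)


class TestCatchupCount:
    def _summary(self, pca, lle, im, counts=(10, 50, 100)):
        rows = []
        for c, p, l, i in zip(counts, pca, lle, im):
            rows += [
                {"method": "PCA", "n_diff": c, "mean": p},
                {"method": "LLE", "n_diff": c, "mean": l},
                {"method": "IM", "n_diff": c, "mean": i},
            ]
        return pd.DataFrame(rows)

    def test_first_count_within_margin_is_returned(self):
        s = self._summary(pca=[0.5, 0.69, 0.9], lle=[0.7, 0.7, 0.9], im=[0.6, 0.6, 0.85])
        assert pca_catchup_count(s, margin=0.02) == 50.0

    def test_never_catching_up_is_infinite(self):
        s = self._summary(pca=[0.5, 0.5, 0.5], lle=[0.8, 0.8, 0.8], im=[0.7, 0.7, 0.7])
        assert pca_catchup_count(s) == np.inf
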