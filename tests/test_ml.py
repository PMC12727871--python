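"""Embedding, clustering, cluster-label matching, feature ranking, repetition."""

import numpy as np
import pytest

from ceikit.features import FeatureMatrix
from ceikit.ml import (
    ClusterAssignment,
    cluster_hdbscan,
    discriminative_power,
    embedding_quality,
    fit_embedding,
    match_clusters_to_labels,
    overlap_coefficient,
    project,
    repeat_with_seeds,
    standardize,
)


def make_blobs(n_per=1000, dims=20, separation=10.0, seed=0):
    """Two isotropic unit-SD Gaussian blobs with centroids ``separation``
    apart (offset spread evenly over all dimensions)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per, dims))
    b = rng.normal(size=(n_per, dims))
    b += separation / np.sqrt(dims)
    X = np.vstack([a, b])
    labels = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
    names = tuple(f"f{i}" for i in range(dims))
    return FeatureMatrix(names, X, labels)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        fm = make_blobs(200, 5)
        std, params = standardize(fm)
        assert np.abs(std.values.mean(axis=0)).max() < 1e-12
        assert np.allclose(std.values.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        fm = FeatureMatrix(("a", "b"), np.column_stack([np.ones(50), np.arange(50.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            std, params = standardize(fm)
        assert std.names == ("b",)

    def test_all_constant_raises(self):
        fm = FeatureMatrix(("a",), np.ones((50, 1)))
        with pytest.raises(ValueError):
            standardize(fm)

    def test_stored_parameters_reproduce_training_matrix(self):
        fm = make_blobs(100, 4)
        std, params = standardize(fm)
        again = params.apply(fm)
        assert np.allclose(std.values, again.values, atol=1e-12)


class TestEmbedding:
    def test_separated_blobs_embed_separably(self):
        fm = make_blobs(1000, 20, separation=10.0)
        model, coords = fit_embedding(fm, "umap", seed=1)
        sil, db = embedding_quality(coords, fm.labels)
        assert coords.shape == (2000, 2)
        assert sil > 0.9

    def test_same_seed_reproduces_coordinates(self):
        fm = make_blobs(300, 8)
        _, c1 = fit_embedding(fm, "umap", seed=5)
        _, c2 = fit_embedding(fm, "umap", seed=5)
        assert np.allclose(c1, c2, atol=1e-12)

    def test_pca_and_lda_run(self):
        fm = make_blobs(200, 6)
        _, c_pca = fit_embedding(fm, "pca", seed=0)
        assert c_pca.shape == (400, 2)
        model, c_lda = fit_embedding(fm, "lda", seed=0)
        assert c_lda.shape[1] == 1  # two classes -> one discriminant axis

    def test_supervised_without_labels_and_unknown_method_raise(self):
        fm = FeatureMatrix(("a", "b"), np.random.default_rng(0).normal(size=(100, 2)))
        with pytest.raises(ValueError, match="labels"):
            fit_embedding(fm, "supervised_umap")
        with pytest.raises(ValueError, match="unknown method"):
            fit_embedding(fm, "isomap")


class TestProjection:
    def test_projected_training_data_stays_with_its_class(self):
        fm = make_blobs(500, 10)
        model, coords = fit_embedding(fm, "umap", seed=2)
        proj = project(model, fm)
        # projection reproduces training coordinates to method tolerance:
        # every projected point lies near its own class centroid
        for cls in ("a", "b"):
            mask = fm.labels == cls
            centroid = coords[mask].mean(axis=0)
            other = coords[~mask].mean(axis=0)
            d_own = np.linalg.norm(proj[mask] - centroid, axis=1)
            d_other = np.linalg.norm(proj[mask] - other, axis=1)
            assert (d_own < d_other).mean() > 0.99

    def test_empty_input_gives_empty_output(self):
        fm = make_blobs(200, 5)
        model, _ = fit_embedding(fm, "umap", seed=0)
        empty = FeatureMatrix(fm.names, np.empty((0, 5)))
        assert project(model, empty).shape == (0, 2)

    def test_schema_mismatch_lists_features(self):
        fm = make_blobs(200, 5)
        model, _ = fit_embedding(fm, "pca", seed=0)
        wrong = FeatureMatrix(("f0", "f1", "f2", "f3", "weird"),
                              np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="weird"):
            project(model, wrong)

    def test_tsne_has_no_out_of_sample_transform(self):
        fm = make_blobs(100, 5)
        model, _ = fit_embedding(fm, "tsne", seed=0, params={"perplexity": 20.0})
        with pytest.raises(ValueError, match="t-SNE"):
            project(model, fm)


class TestClustering:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(3)
        coords = np.vstack([rng.normal(size=(600, 2)), rng.normal(size=(600, 2)) + [10, 0]])
        assignment = cluster_hdbscan(coords)
        assert assignment.n_clusters == 2
        assert (assignment.labels < 0).mean() < 0.01

    def test_single_blob_single_cluster(self):
        coords = np.random.default_rng(4).normal(size=(500, 2))
        assert cluster_hdbscan(coords).n_clusters == 1

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="min_cluster_size"):
            cluster_hdbscan(np.zeros((10, 2)))

    def test_cluster_ids_must_be_contiguous(self):
        with pytest.raises(ValueError):
            ClusterAssignment(np.array([0, 2, 2]), 2)


class TestMatching:
    def test_perfect_clustering(self):
        assignment = ClusterAssignment(np.array([0] * 5 + [1] * 5), 2)
        labels = ["a"] * 5 + ["b"] * 5
        report = match_clusters_to_labels(assignment, labels)
        assert report.recovery == {"a": 1.0, "b": 1.0}
        assert report.misclassification_rate == 0.0
        assert report.n_noise == 0

    def test_report_invariant_under_cluster_id_permutation(self):
        labels = ["a"] * 5 + ["b"] * 5
        r1 = match_clusters_to_labels(ClusterAssignment(np.array([0] * 5 + [1] * 5), 2), labels)
        r2 = match_clusters_to_labels(ClusterAssignment(np.array([1] * 5 + [0] * 5), 2), labels)
        assert r1.recovery == r2.recovery
        assert r1.misclassification_rate == r2.misclassification_rate

    def test_all_noise_reports_zero_assigned(self):
        assignment = ClusterAssignment(np.full(10, -1), 0)
        report = match_clusters_to_labels(assignment, ["a"] * 5 + ["b"] * 5)
        assert report.n_noise == 10
        assert report.misclassification_rate == 0.0
        assert report.recovery == {"a": 0.0, "b": 0.0}

    def test_empty_assignment_raises(self):
        with pytest.raises(ValueError, match="empty"):
            match_clusters_to_labels(ClusterAssignment(np.array([], dtype=int), 0), [])


class TestDiscriminativePower:
    def test_label_independent_feature_ranks_last(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 400 + [1] * 400)
        X = np.column_stack([
            y + 0.3 * rng.normal(size=800),       # informative
            2 * y + 0.5 * rng.normal(size=800),   # informative
            rng.normal(size=800),                 # pure noise
        ])
        fm = FeatureMatrix(("good1", "good2", "noise"), X,
                           np.array(["a", "b"])[y].astype(object))
        report = discriminative_power(fm, n_repeats=10, seed=0)
        assert report.ranking()[-1][0] == "noise"
        assert np.allclose(report.mean_importance.sum(), 1.0, atol=1e-9)
        assert np.all(report.mean_importance >= 0)
        assert report.std_error.shape == report.mean_importance.shape

    def test_single_class_and_too_few_repeats_raise(self):
        fm = FeatureMatrix(("a",), np.random.default_rng(0).normal(size=(50, 1)),
                           np.array(["x"] * 50, dtype=object))
        with pytest.raises(ValueError, match="classes"):
            discriminative_power(fm, n_repeats=5)
        fm2 = FeatureMatrix(("a",), np.random.default_rng(0).normal(size=(50, 1)),
                            np.array(["x", "y"] * 25, dtype=object))
        with pytest.raises(ValueError, match="n_repeats"):
            discriminative_power(fm2, n_repeats=1)


class TestEmbeddingQuality:
    def test_matches_brute_force_on_four_point_example(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = ["a", "a", "b", "b"]
        sil, db = embedding_quality(coords, labels)
        # brute force: a = 1 for every point; b = (10 + sqrt(101))/2
        b = (10.0 + np.sqrt(101.0)) / 2.0
        assert sil == pytest.approx((b - 1.0) / b, abs=1e-12)
        # centroid scatters 0.5 each, centroid distance 10
        assert db == pytest.approx((0.5 + 0.5) / 10.0, abs=1e-12)

    def test_well_separated_clusters_approach_silhouette_one(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 1e-3, (50, 2)), rng.normal(0, 1e-3, (50, 2)) + 100])
        sil, _ = embedding_quality(coords, ["a"] * 50 + ["b"] * 50)
        assert sil > 0.999

    def test_superimposed_clusters_score_near_zero(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(200, 2))
        sil, _ = embedding_quality(coords, ["a", "b"] * 100)
        assert sil < 0.1

    def test_degenerate_labels_raise(self):
        with pytest.raises(ValueError):
            embedding_quality(np.zeros((4, 2)), ["a", "a", "a", "a"])
        with pytest.raises(ValueError):
            embedding_quality(np.zeros((3, 2)), ["a", "a", "b"])


class TestRepetition:
    def test_deterministic_stage_has_zero_se(self):
        summary = repeat_with_seeds(lambda s: {"x": 3.0}, n_repeats=5, base_seed=0)
        assert summary.mean == {"x": 3.0}
        assert summary.std_error == {"x": 0.0}

    def test_single_repeat_reports_absent_se(self):
        summary = repeat_with_seeds(lambda s: {"x": float(s)}, n_repeats=1, base_seed=9)
        assert summary.std_error is None
        assert summary.seeds == (9,)

    def test_se_scales_inversely_with_sqrt_repeats(self):
        stage = lambda s: {"x": float(np.random.default_rng(s).normal())}
        se1 = repeat_with_seeds(stage, 200, base_seed=0).std_error["x"]
        se2 = repeat_with_seeds(stage, 800, base_seed=1000).std_error["x"]
        assert 1.5 < se1 / se2 < 2.7  # ideally 2


class TestOverlapCoefficient:
    def test_disjoint_and_identical_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 5000)
        assert overlap_coefficient(a, a + 100) == pytest.approx(0.0, abs=1e-12)
        assert overlap_coefficient(a, a) == pytest.approx(1.0, abs=1e-12)
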