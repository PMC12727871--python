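"""Machine-learning pipeline for structure differentiation.

The workflow mirrors standard practice for momentum-space event data:
standardize features, reduce to two dimensions (UMAP by default, supervised
UMAP / PCA / t-SNE / LDA as alternatives), find clusters by density
(HDBSCAN), map clusters to structure labels, and rank features by their
discriminative power with a Random Forest, repeating stochastic stages over
a deterministic seed schedule and reporting mean ± standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .features import FeatureMatrix

__all__ = [
    "EmbeddingModel",
    "classify_by_projection",
    "overlap_coefficient",
    "ClusterAssignment",
    "ClassificationReport",
    "DiscriminativePowerReport",
    "RepeatSummary",
    "standardize",
    "fit_embedding",
    "project",
    "cluster_hdbscan",
    "match_clusters_to_labels",
    "discriminative_power",
    "embedding_quality",
    "repeat_with_seeds",
]

_METHODS = ("umap", "supervised_umap", "pca", "tsne", "lda")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardization:
    """Per-feature z-score parameters fit on training data.

    ``names`` are the retained columns; ``input_names`` is the full training
    schema including any zero-variance columns dropped at fit time (these are
    tolerated, and ignored, when applying to new data).
    """

    names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray
    input_names: tuple[str, ...] = ()

    def apply(self, features: FeatureMatrix) -> FeatureMatrix:
        known = set(self.input_names) | set(self.names)
        missing = set(self.names) - set(features.names)
        extra = set(features.names) - known
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        sub = features.select(list(self.names))
        return FeatureMatrix(
            self.names, (sub.values - self.mean) / self.std, sub.labels, sub.event_ids
        )


def standardize(features: FeatureMatrix) -> tuple[FeatureMatrix, Standardization]:
    """Z-score each column on this data; zero-variance columns are dropped
    with a warning.  Returns the standardized matrix and the fitted
    parameters for later reuse on held-out data."""
    std = features.values.std(axis=0)
    keep = std > 1e-12
    if not np.any(keep):
        raise ValueError("all feature columns have zero variance")
    if not np.all(keep):
        dropped = [n for n, k in zip(features.names, keep) if not k]
        warnings.warn(f"dropping zero-variance feature columns: {dropped}")
    names = tuple(n for n, k in zip(features.names, keep) if k)
    params = Standardization(
        names, features.values[:, keep].mean(axis=0), std[keep], input_names=features.names
    )
    return params.apply(features), params


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    """A fitted 2D embedding supporting projection of new events."""

    method: str
    params: dict
    seed: int
    standardization: Standardization
    estimator: object
    training_coords: np.ndarray
    classes: tuple | None = None  # label classes, supervised methods only

    def feature_names(self) -> tuple[str, ...]:
        return self.standardization.names


def _encode_labels(labels: Sequence) -> tuple[np.ndarray, tuple]:
    classes = tuple(sorted(set(map(str, labels))))
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[str(l)] for l in labels]), classes


def fit_embedding(
    features: FeatureMatrix,
    method: str = "umap",
    params: dict | None = None,
    labels: Sequence | None = None,
    seed: int = 0,
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit a 2D embedding of the (standardized) feature matrix.

    ``supervised_umap`` and ``lda`` require per-event labels; supervised UMAP
    optimizes two nonlinear combinations of the input features that maximize
    class separation, which is what lets a simulation-trained latent space
    classify held-out or experimental events after :func:`project`.
    Deterministic given ``seed``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    params = dict(params or {})
    if labels is None and features.labels is not None:
        labels = features.labels
    supervised = method in ("supervised_umap", "lda")
    if supervised and labels is None:
        raise ValueError(f"method {method!r} requires labels")

    X_std, standardization = standardize(features)
    X = X_std.values
    classes = None
    y = None
    if supervised:
        y, classes = _encode_labels(labels)

    if method in ("umap", "supervised_umap"):
        import umap  # deferred: numba compilation is slow at import time

        defaults = {"n_neighbors": 15, "min_dist": 0.1, "n_components": 2}
        defaults.update(params)
        est = umap.UMAP(random_state=seed, **defaults)
        coords = est.fit_transform(X, y=y) if supervised else est.fit_transform(X)
    elif method == "pca":
        est = PCA(n_components=params.pop("n_components", 2), random_state=seed, **params)
        coords = est.fit_transform(X)
    elif method == "tsne":
        defaults = {"n_components": 2, "init": "pca", "perplexity": 30.0}
        defaults.update(params)
        est = TSNE(random_state=seed, **defaults)
        coords = est.fit_transform(X)
    else:  # lda
        n_comp = min(params.pop("n_components", 2), len(classes) - 1)
        est = LinearDiscriminantAnalysis(n_components=n_comp, **params)
        coords = est.fit_transform(X, y)

    model = EmbeddingModel(
        method=method,
        params=params,
        seed=seed,
        standardization=standardization,
        estimator=est,
        training_coords=np.asarray(coords, float),
        classes=classes,
    )
    return model, model.training_coords


def project(model: EmbeddingModel, features: FeatureMatrix) -> np.ndarray:
    """Project new events into a fitted embedding without refitting.

    The stored standardization is applied first; the feature schema must
    match the training schema.  t-SNE has no out-of-sample transform.
    """
    if features.n_events == 0:
        return np.empty((0, model.training_coords.shape[1]))
    X = model.standardization.apply(features).values
    if model.method == "tsne":
        raise ValueError("t-SNE does not support projecting new data; use umap/pca/lda")
    return np.asarray(model.estimator.transform(X), float)


# ---------------------------------------------------------------------------
# Clustering and cluster-label matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    """Per-event cluster ids, −1 = noise; ids contiguous from 0."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        ids = np.unique(labels[labels >= 0])
        if len(ids) and (ids != np.arange(len(ids))).any():
            raise ValueError("cluster ids must be contiguous from 0")


def cluster_hdbscan(
    coordinates: np.ndarray,
    min_cluster_size: int | None = None,
    min_samples: int | None = None,
    allow_single_cluster: bool = True,
) -> ClusterAssignment:
    """Density clustering of embedded coordinates with HDBSCAN.

    No cluster count is supplied; low-density points get the noise label −1.
    ``min_cluster_size`` defaults to max(50, 1% of the events).  The root
    cluster is allowed (``allow_single_cluster``) so unimodal data yields one
    cluster rather than all-noise.
    """
    coordinates = np.asarray(coordinates, float)
    n = coordinates.shape[0]
    if min_cluster_size is None:
        min_cluster_size = max(50, int(0.01 * n))
    if n < min_cluster_size:
        raise ValueError(f"need at least min_cluster_size={min_cluster_size} points, got {n}")
    est = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        allow_single_cluster=allow_single_cluster,
    )
    labels = est.fit_predict(coordinates)
    # compact ids to be contiguous from 0
    ids = np.unique(labels[labels >= 0])
    remap = {old: new for new, old in enumerate(ids)}
    labels = np.array([remap.get(l, -1) for l in labels])
    return ClusterAssignment(labels, n_clusters=len(ids))


@dataclass(frozen=True)
class ClassificationReport:
    """Cluster-to-label matching summary.

    recovery[c] = events of true class c assigned to c / true count of c;
    misclassification_rate = wrongly assigned / total assigned (noise events
    are counted separately, not as errors).
    """

    mapping: dict
    classes: tuple
    assigned_counts: dict
    true_counts: dict
    recovery: dict
    misclassification_rate: float
    n_noise: int
    purity: dict  # per-cluster majority fraction

    def as_dict(self) -> dict:
        return {
            "mapping": {str(k): str(v) for k, v in self.mapping.items()},
            "classes": [str(c) for c in self.classes],
            "assigned_counts": {str(k): int(v) for k, v in self.assigned_counts.items()},
            "true_counts": {str(k): int(v) for k, v in self.true_counts.items()},
            "recovery": {str(k): float(v) for k, v in self.recovery.items()},
            "misclassification_rate": float(self.misclassification_rate),
            "n_noise": int(self.n_noise),
            "purity": {str(k): float(v) for k, v in self.purity.items()},
        }


def match_clusters_to_labels(
    assignment: ClusterAssignment, true_labels: Sequence
) -> ClassificationReport:
    """Map each cluster to its majority true label and score the assignment.

    Ties break toward the larger class.  Invariant under any permutation of
    the cluster ids.
    """
    labels = np.asarray([str(l) for l in true_labels])
    if len(labels) != len(assignment.labels):
        raise ValueError("true_labels length must match the assignment")
    if len(labels) == 0:
        raise ValueError("empty assignment")
    classes = tuple(sorted(set(labels)))
    class_sizes = {c: int((labels == c).sum()) for c in classes}
    mapping: dict[int, str] = {}
    purity: dict[int, float] = {}
    for cid in range(assignment.n_clusters):
        members = labels[assignment.labels == cid]
        counts = {c: int((members == c).sum()) for c in classes}
        best = max(classes, key=lambda c: (counts[c], class_sizes[c]))
        mapping[cid] = best
        purity[cid] = counts[best] / len(members) if len(members) else 0.0

    assigned = assignment.labels >= 0
    predicted = np.array([mapping[l] if l >= 0 else "" for l in assignment.labels])
    n_assigned = int(assigned.sum())
    n_wrong = int((predicted[assigned] != labels[assigned]).sum())
    recovery = {}
    assigned_counts = {}
    for c in classes:
        assigned_counts[c] = int((predicted == c).sum())
        correct = int(((predicted == c) & (labels == c)).sum())
        recovery[c] = correct / class_sizes[c] if class_sizes[c] else 0.0
    return ClassificationReport(
        mapping=mapping,
        classes=classes,
        assigned_counts=assigned_counts,
        true_counts=class_sizes,
        recovery=recovery,
        misclassification_rate=(n_wrong / n_assigned) if n_assigned else 0.0,
        n_noise=int((~assigned).sum()),
        purity=purity,
    )


def classify_by_projection(
    train_coords: np.ndarray,
    train_labels: Sequence,
    test_coords: np.ndarray,
    test_labels: Sequence | None = None,
    min_cluster_size: int | None = None,
) -> dict:
    """Classify held-out events via a shared embedding space.

    Train and test coordinates are clustered jointly with HDBSCAN; each
    cluster is named by its majority training label, and held-out events
    inherit the name of their cluster (noise stays unassigned).  When test
    labels are given, the report includes per-class recovery (correctly
    assigned / true count) and the misclassification rate over assigned
    events.
    """
    train_coords = np.asarray(train_coords, float)
    test_coords = np.asarray(test_coords, float)
    all_coords = np.vstack([train_coords, test_coords])
    assignment = cluster_hdbscan(all_coords, min_cluster_size)
    n_train = len(train_coords)
    train_match = match_clusters_to_labels(
        ClusterAssignment(assignment.labels[:n_train], assignment.n_clusters), train_labels
    )
    mapping = train_match.mapping
    test_assign = assignment.labels[n_train:]
    predicted = np.array([mapping.get(l, "") if l >= 0 else "" for l in test_assign])
    report: dict = {
        "n_clusters": assignment.n_clusters,
        "n_test": int(len(test_coords)),
        "n_test_noise": int((test_assign < 0).sum()),
        "test_assigned_counts": {
            str(c): int((predicted == c).sum()) for c in train_match.classes
        },
    }
    if test_labels is not None:
        truth = np.array([str(l) for l in test_labels])
        assigned = predicted != ""
        recovery = {}
        true_counts = {}
        for c in sorted(set(truth)):
            n_true = int((truth == c).sum())
            true_counts[str(c)] = n_true
            recovery[str(c)] = (
                float(((predicted == c) & (truth == c)).sum() / n_true) if n_true else 0.0
            )
        report["test_true_counts"] = true_counts
        report["recovery"] = recovery
        n_assigned = int(assigned.sum())
        report["misclassification_rate"] = (
            float((predicted[assigned] != truth[assigned]).sum() / n_assigned)
            if n_assigned
            else 0.0
        )
    return report


def overlap_coefficient(a: np.ndarray, b: np.ndarray, bins: int = 60) -> float:
    """Histogram overlap of two 1D samples: sum of per-bin minimum of the two
    normalized histograms over a common range (1 = identical, 0 = disjoint)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
    ha = np.histogram(a, bins=bins, range=(lo, hi))[0] / len(a)
    hb = np.histogram(b, bins=bins, range=(lo, hi))[0] / len(b)
    return float(np.minimum(ha, hb).sum())


# ---------------------------------------------------------------------------
# Discriminative power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminativePowerReport:
    """Mean ± SE of Random-Forest impurity-reduction importances over
    repeated fits with different random states."""

    feature_names: tuple[str, ...]
    mean_importance: np.ndarray
    std_error: np.ndarray
    n_repeats: int
    seeds: tuple[int, ...]
    rank1_counts: dict = field(default_factory=dict)  # feature -> times ranked first

    def ranking(self) -> list[tuple[str, float, float]]:
        order = np.argsort(self.mean_importance)[::-1]
        return [
            (self.feature_names[i], float(self.mean_importance[i]), float(self.std_error[i]))
            for i in order
        ]

    def top_feature(self) -> str:
        return self.ranking()[0][0]

    def as_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "importance": {
                n: {"mean": float(m), "se": float(s)}
                for n, m, s in zip(self.feature_names, self.mean_importance, self.std_error)
            },
            "rank1_counts": {k: int(v) for k, v in self.rank1_counts.items()},
        }


def discriminative_power(
    features: FeatureMatrix,
    labels: Sequence | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
) -> DiscriminativePowerReport:
    """Rank features by Random-Forest impurity-reduction importance.

    One forest (bootstrap samples, random feature subsets at each split) is
    fit per repeat with seed ``seed + k``; each repeat's importances sum to 1.
    The report carries the mean, the standard error SD/sqrt(n_repeats), and
    how often each feature ranked first.
    """
    if labels is None:
        labels = features.labels
    if labels is None:
        raise ValueError("labels are required")
    y, classes = _encode_labels(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    X = features.values
    importances = np.empty((n_repeats, X.shape[1]))
    seeds = tuple(seed + k for k in range(n_repeats))
    for k, s in enumerate(seeds):
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=s, n_jobs=1)
        clf.fit(X, y)
        importances[k] = clf.feature_importances_
    mean = importances.mean(axis=0)
    se = importances.std(axis=0, ddof=1) / np.sqrt(n_repeats)
    rank1 = np.argmax(importances, axis=1)
    counts: dict[str, int] = {}
    for idx in rank1:
        counts[features.names[idx]] = counts.get(features.names[idx], 0) + 1
    return DiscriminativePowerReport(features.names, mean, se, n_repeats, seeds, counts)


# ---------------------------------------------------------------------------
# Embedding quality and seeded repetition
# ---------------------------------------------------------------------------

def embedding_quality(coordinates: np.ndarray, labels: Sequence) -> tuple[float, float]:
    """(Silhouette score, Davies–Bouldin index) of labeled coordinates.

    Silhouette in [−1, 1], higher is better; DB ≥ 0, lower is better.
    """
    coordinates = np.asarray(coordinates, float)
    y, classes = _encode_labels(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct labels")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("each label needs at least 2 points")
    return float(silhouette_score(coordinates, y)), float(davies_bouldin_score(coordinates, y))


@dataclass(frozen=True)
class RepeatSummary:
    """Aggregated scalar outputs of a seeded stage run n times."""

    per_repeat: tuple
    mean: dict
    std_error: dict | None  # None when n_repeats == 1
    seeds: tuple[int, ...]


def repeat_with_seeds(
    stage: Callable[[int], Mapping[str, float]],
    n_repeats: int,
    base_seed: int = 0,
) -> RepeatSummary:
    """Run ``stage(seed)`` for seeds base_seed, base_seed+1, … and aggregate.

    ``stage`` returns a mapping of scalar outputs; the summary holds their
    mean and standard error (SD/sqrt(n), absent for a single repeat).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seeds = tuple(base_seed + k for k in range(n_repeats))
    results = [dict(stage(s)) for s in seeds]
    keys = results[0].keys()
    mean = {k: float(np.mean([r[k] for r in results])) for k in keys}
    if n_repeats == 1:
        se = None
    else:
        se = {
            k: float(np.std([r[k] for r in results], ddof=1) / np.sqrt(n_repeats))
            for k in keys
        }
    return RepeatSummary(tuple(results), mean, se, seeds)
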