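"""Agglomerative clustering of SOM neurons with silhouette-based k selection.

Neuron codebook vectors are grouped by complete-linkage agglomerative
clustering (Euclidean distance); the number of macrostate clusters is the
one maximizing the mean silhouette over a candidate range.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .som_core import SOMModel


@dataclass
class NeuronClustering:
    """Cluster label per neuron plus the linkage and silhouette records."""

    k: int
    labels: np.ndarray  # int labels 1..k, one per neuron
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge record
    silhouette_profile: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    @property
    def merge_heights(self) -> np.ndarray:
        return np.asarray(self.linkage_matrix)[:, 2]

    def to_json(self, path) -> None:
        blob = {
            "k": self.k,
            "labels": self.labels.tolist(),
            "linkage": np.asarray(self.linkage_matrix).tolist(),
            "silhouette_profile": {str(k): v for k, v in
                                   self.silhouette_profile.items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def from_json(cls, path) -> "NeuronClustering":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(k=blob["k"], labels=np.array(blob["labels"]),
                   linkage_matrix=np.array(blob["linkage"]),
                   silhouette_profile={int(k): v for k, v in
                                       blob["silhouette_profile"].items()})


def cluster_neurons(model: SOMModel, k: int) -> NeuronClustering:
    """Complete-linkage (Euclidean) clustering of the codebook into k groups."""
    n = model.codebook.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    Z = linkage(model.codebook, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber to 1..k in first-appearance order for determinism
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order) + 1
        labels[i] = order[lab]
    return NeuronClustering(k=k, labels=labels, linkage_matrix=Z)


def silhouette_mean(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b-a)/max(a,b); singleton clusters score 0."""
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(vectors, labels, metric="euclidean"))


def select_k(model: SOMModel, k_min: int = 2, k_max: int = 10,
             features=None, sample_size: int = 2048) -> NeuronClustering:
    """Clustering at the silhouette-optimal k (ties go to the smaller k).

    When `features` (a FeatureMatrix or array of the frames the map was
    trained on) is given, the silhouette is evaluated on the frames
    carrying each candidate clustering's labels through their
    best-matching units; neurons that attract no frames then cannot
    manufacture clusters of their own, which makes the choice robust to
    interpolating dead units. Without `features` the silhouette is
    computed on the neuron codebook vectors directly. Frame-level
    evaluation subsamples at most `sample_size` frames (deterministic).
    """
    n = model.codebook.shape[0]
    if k_max > n:
        raise ValueError("k_max exceeds the number of neurons")

    frame_labels_base = None
    X = None
    if features is not None:
        from .som_core import assign_bmu  # local import avoids a cycle

        X = np.asarray(getattr(features, "values", features), dtype=float)
        frame_labels_base = assign_bmu(X, model).neuron
        if X.shape[0] > sample_size:
            rng = np.random.default_rng(model.params.seed)
            keep = rng.choice(X.shape[0], size=sample_size, replace=False)
            X = X[keep]
            frame_labels_base = frame_labels_base[keep]

    profile: dict[int, float] = {}
    clusterings: dict[int, NeuronClustering] = {}
    for k in range(k_min, k_max + 1):
        c = cluster_neurons(model, k)
        clusterings[k] = c
        if frame_labels_base is not None:
            labels = c.labels[frame_labels_base]
            if len(np.unique(labels)) < 2:
                profile[k] = -1.0
            else:
                profile[k] = silhouette_mean(X, labels)
        elif len(np.unique(c.labels)) == n:
            # all singletons -> silhouette undefined; score it -1
            profile[k] = -1.0
        else:
            profile[k] = silhouette_mean(model.codebook, c.labels)
    best_k = max(profile, key=lambda k: (profile[k], -k))
    best = clusterings[best_k]
    best.silhouette_profile = profile
    return best
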