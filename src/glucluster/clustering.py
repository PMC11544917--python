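"""Hierarchical Ward clustering of nocturnal glucose series.

Training series (vectors in R^72, mmol/L) are clustered agglomeratively with
Ward's minimum-variance criterion; the number of clusters is chosen by the
silhouette score; each cluster is summarized by its medoid (the member series
minimizing the summed Euclidean distance to all members). New series are
assigned to the cluster with the nearest medoid, optionally on a causal
prefix of the night. A noise-perturbation stability score (mean adjusted Rand
index over reclustered perturbed copies) quantifies how robust the partition
is.

Distances are plain Euclidean on raw glucose vectors: series share units and
a fixed nightly time grid, so no normalization or warping is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .exceptions import ConfigurationError, DataError


@dataclass
class LinkageHistory:
    """Agglomerative merge sequence.

    ``merges`` follows the scipy convention: leaves are 0..n-1 and the merge
    at step i creates cluster ``n_leaves + i``. ``merge_cost`` is the increase
    in total within-cluster sum of squared Euclidean deviations (Ward's
    objective), which is nondecreasing along the sequence.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int


@dataclass
class ClusterModel:
    """Fitted clustering: labels, medoids, and quality scores.

    Labels run 1..k. ``medoid_ids[j-1]`` is the training-row index of cluster
    j's medoid and ``medoid_series[j-1]`` the corresponding glucose vector.
    """

    k: int
    labels: np.ndarray
    medoid_ids: np.ndarray
    medoid_series: np.ndarray
    metric: str = "euclidean"
    silhouette: float | None = None
    stability: float | None = None

    @property
    def series_length(self) -> int:
        return self.medoid_series.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "k": int(self.k),
            "metric": self.metric,
            "labels": self.labels.tolist(),
            "medoid_ids": self.medoid_ids.tolist(),
            "silhouette": None if self.silhouette is None else float(self.silhouette),
            "stability": None if self.stability is None else float(self.stability),
        }

    def save(self, json_path, medoid_csv_path) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        pd.DataFrame(
            self.medoid_series,
            index=pd.Index(range(1, self.k + 1), name="cluster"),
            columns=[f"g{i:02d}" for i in range(self.series_length)],
        ).to_csv(medoid_csv_path)

    @classmethod
    def load(cls, json_path, medoid_csv_path) -> "ClusterModel":
        with open(json_path) as fh:
            meta = json.load(fh)
        medoids = pd.read_csv(medoid_csv_path, index_col=0).to_numpy(dtype=float)
        return cls(
            k=meta["k"],
            labels=np.asarray(meta["labels"], dtype=int),
            medoid_ids=np.asarray(meta["medoid_ids"], dtype=int),
            medoid_series=medoids,
            metric=meta.get("metric", "euclidean"),
            silhouette=meta.get("silhouette"),
            stability=meta.get("stability"),
        )


# ---------------------------------------------------------------------------
# Ward linkage and tree cutting
# ---------------------------------------------------------------------------

def ward_linkage(series: np.ndarray) -> LinkageHistory:
    """Ward's agglomerative merge sequence for an (n, L) series matrix.

    Each step merges the pair of clusters whose union least increases the
    total within-cluster sum of squared deviations from cluster means,
    continuing until a single cluster remains.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least two series")
    if np.isnan(series).any():
        raise DataError("series must contain no missing values")
    Z = linkage(series, method="ward")
    # scipy reports the Ward distance d = sqrt(2 * delta-ESS); store delta-ESS.
    merges = [
        (int(a), int(b), float(d) ** 2 / 2.0) for a, b, d, _ in Z
    ]
    return LinkageHistory(merges=merges, n_leaves=series.shape[0])


def cut_to_k(history: LinkageHistory, k: int) -> np.ndarray:
    """Labels obtained by undoing the last k-1 merges, renumbered 1..k in
    order of first occurrence along the rows."""
    n = history.n_leaves
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} out of range [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _) in enumerate(history.merges[: n - k]):
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    labels = np.empty(n, dtype=int)
    renumber: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in renumber:
            renumber[root] = len(renumber) + 1
        labels[i] = renumber[root]
    return labels


# ---------------------------------------------------------------------------
# Silhouette-guided choice of k
# ---------------------------------------------------------------------------

def silhouette(series: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score with Euclidean distance.

    Uses the convention that singleton-cluster points score 0; the degenerate
    all-singleton partition therefore scores exactly 0. A single-cluster
    partition has no between-cluster term and raises.
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ConfigurationError("silhouette undefined for a single cluster")
    if n < 3:
        raise DataError("need at least 3 series")
    if len(uniq) == n:
        return 0.0
    return float(silhouette_score(series, labels, metric="euclidean"))


def select_num_clusters(
    series: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    history: LinkageHistory | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose k maximizing the silhouette over an inclusive range.

    Ties break to the smallest k. Returns the chosen k and the full per-k
    silhouette table for expert inspection.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo > k_hi:
        raise ConfigurationError("empty k range")
    if k_lo < 2 or k_hi > n - 1:
        raise ConfigurationError(f"k_range must lie within [2, {n - 1}]")
    if history is None:
        history = ward_linkage(series)
    rows = []
    for k in range(k_lo, k_hi + 1):
        rows.append({"k": k, "silhouette": silhouette(series, cut_to_k(history, k))})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["silhouette"].idxmax(), "k"])  # idxmax: first max
    return best, table


# ---------------------------------------------------------------------------
# Medoids and nearest-medoid assignment
# ---------------------------------------------------------------------------

def compute_medoids(series: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cluster medoid row indices, ordered by cluster label.

    The medoid is the member minimizing the sum of Euclidean distances to all
    members of its cluster; ties break to the lowest row index.
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    medoid_ids = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        dists = cdist(series[idx], series[idx]).sum(axis=1)
        medoid_ids.append(idx[int(np.argmin(dists))])
    return np.asarray(medoid_ids, dtype=int)


def assign_nearest_cluster(
    prefix: np.ndarray, model: ClusterModel
) -> tuple[int, np.ndarray]:
    """Nearest-medoid cluster for a (possibly truncated) glucose vector.

    The Euclidean distance is taken between the prefix and the first
    ``len(prefix)`` components of every medoid, so assignment never looks at
    future readings. Returns (cluster id in 1..k, distance vector d').
    Equidistant medoids resolve to the lowest cluster id.
    """
    prefix = np.asarray(prefix, dtype=float)
    P = len(prefix)
    if P > model.series_length:
        raise ConfigurationError(
            f"prefix length {P} exceeds series length {model.series_length}"
        )
    d = np.linalg.norm(model.medoid_series[:, :P] - prefix[None, :], axis=1)
    return int(np.argmin(d)) + 1, d


# ---------------------------------------------------------------------------
# Stability assessment
# ---------------------------------------------------------------------------

def stability_assessment(
    series: np.ndarray,
    k: int,
    n_reps: int = 100,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> float:
    """Noise-perturbation stability of the k-cluster Ward partition.

    Every value is perturbed with independent N(0, noise_sd) noise (mmol/L),
    the perturbed matrix is reclustered and cut to k, and the adjusted Rand
    index against the unperturbed partition is recorded; the mean over
    ``n_reps`` repetitions is returned (1 = perfectly stable).
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    series = np.asarray(series, dtype=float)
    base = cut_to_k(ward_linkage(series), k)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_reps)
    for rep in range(n_reps):
        noisy = series + rng.normal(0.0, noise_sd, size=series.shape)
        scores[rep] = adjusted_rand_score(base, cut_to_k(ward_linkage(noisy), k))
    return float(scores.mean())


# ---------------------------------------------------------------------------
# One-call model fit
# ---------------------------------------------------------------------------

def fit_cluster_model(
    series: np.ndarray,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
    stability_reps: int = 0,
    stability_noise_sd: float = 0.3,
    seed: int = 0,
) -> ClusterModel:
    """Cluster a training matrix end to end.

    If ``k`` is None it is chosen by silhouette over ``k_range`` (a fixed k
    overrides the automatic choice, mirroring expert override of the score).
    Stability is computed only when ``stability_reps`` > 0, as it requires
    ``stability_reps`` reclusterings.
    """
    series = np.asarray(series, dtype=float)
    history = ward_linkage(series)
    if k is None:
        k, _ = select_num_clusters(series, k_range, history=history)
    labels = cut_to_k(history, k)
    medoid_ids = compute_medoids(series, labels)
    sil = silhouette(series, labels) if k >= 2 else None
    stab = (
        stability_assessment(series, k, stability_reps, stability_noise_sd, seed)
        if stability_reps > 0
        else None
    )
    return ClusterModel(
        k=k,
        labels=labels,
        medoid_ids=medoid_ids,
        medoid_series=series[medoid_ids].copy(),
        silhouette=sil,
        stability=stab,
    )
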