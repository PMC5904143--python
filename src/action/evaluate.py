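"""Kernel k-means clustering and extrinsic partition-quality measures."""

from __future__ import annotations

import numpy as np
from scipy.special import comb
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array

__all__ = ["KernelKMeans", "kernel_kmeans", "clustering_scores", "pairwise_fscore"]


class KernelKMeans(BaseEstimator, ClusterMixin):
    """k-means in the feature space induced by a precomputed kernel.

    The squared distance from point i to the centroid of cluster c is
    ``K_ii - 2 mean_{j in c} K_ij + mean_{j,l in c} K_jl``, so Lloyd
    iterations need only the kernel.  Initialization is by random
    assignment; the best of ``n_init`` runs (lowest inertia) is kept.
    When a cluster empties, the point farthest from its own centroid is
    reassigned to it.

    Parameters
    ----------
    n_clusters : int
    n_init : int, default 100
        Independent random restarts.
    max_iter : int, default 100
    random_state : int or None
        Seed; runs are deterministic given it.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
    inertia_ : float
        Kernel k-means objective of the best run.
    n_iter_ : int
        Iterations used by the best run.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 100,
                 max_iter: int = 100, random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        K = check_array(X, dtype=float)
        n = K.shape[0]
        if K.shape[1] != n:
            raise ValueError("kernel matrix must be square")
        k = int(self.n_clusters)
        if not 2 <= k < n:
            raise ValueError(f"need 2 <= n_clusters < n_samples, got {k}, {n}")
        rng = check_random_state(self.random_state)
        diag = np.diag(K).copy()
        best = None
        for _ in range(self.n_init):
            labels = rng.randint(k, size=n)
            labels[rng.permutation(n)[:k]] = np.arange(k)  # no empty start
            inertia, labels, n_iter = self._lloyd(K, diag, labels, k)
            if best is None or inertia < best[0] - 1e-12:
                best = (inertia, labels, n_iter)
        self.inertia_, self.labels_, self.n_iter_ = best
        return self

    def _lloyd(self, K, diag, labels, k):
        n = K.shape[0]
        for it in range(self.max_iter):
            M = np.zeros((n, k))
            within = np.zeros(k)
            sizes = np.zeros(k)
            for c in range(k):
                mask = labels == c
                sz = mask.sum()
                sizes[c] = sz
                if sz == 0:
                    continue
                Kc = K[:, mask]
                M[:, c] = Kc.mean(axis=1)
                within[c] = Kc[mask].sum() / sz**2
            dist = diag[:, None] - 2.0 * M + within[None, :]
            dist[:, sizes == 0] = np.inf
            new_labels = np.argmin(dist, axis=1)
            # refill any emptied cluster with the worst-fit point
            for c in range(k):
                if not np.any(new_labels == c):
                    donor = np.argmax(dist[np.arange(n), new_labels])
                    new_labels[donor] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        inertia = float(dist[np.arange(n), labels].sum())
        return inertia, labels, it + 1

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kernel_kmeans(K, n_clusters: int, n_init: int = 100, seed: int | None = 0):
    """Functional wrapper around :class:`KernelKMeans`; returns the estimator."""
    return KernelKMeans(
        n_clusters=n_clusters, n_init=n_init, random_state=seed
    ).fit(np.asarray(K, dtype=float))


def pairwise_fscore(pred, truth) -> float:
    """F-score over co-clustered pairs.

    A pair of samples is a true positive if it is co-clustered in both
    partitions; precision and recall are taken over the predicted and true
    co-clustered pairs and combined harmonically.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    cont = contingency_matrix(truth, pred)
    tp = comb(cont, 2).sum()
    pred_pairs = comb(cont.sum(axis=0), 2).sum()
    true_pairs = comb(cont.sum(axis=1), 2).sum()
    if pred_pairs == 0 or true_pairs == 0:
        return 0.0
    precision = tp / pred_pairs
    recall = tp / true_pairs
    if precision + recall == 0:
        return 0.0
    return float(2 * precision * recall / (precision + recall))


def clustering_scores(pred, truth) -> dict[str, float]:
    """Adjusted Rand index, NMI (arithmetic normalization) and pairwise F."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.size} vs {truth.size}"
        )
    return {
        "ari": float(adjusted_rand_score(truth, pred)),
        "nmi": float(
            normalized_mutual_info_score(truth, pred, average_method="arithmetic")
        ),
        "fscore": pairwise_fscore(pred, truth),
    }
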