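"""Base clustering algorithms for ensemble generation.

Each algorithm obeys one contract: ``fn(input, k, seed) -> labels`` with
labels covering a subset of {1..k}, one label per input sample. ``input`` is
either the prepared data matrix (``needs='raw_data'``) or a square
dissimilarity matrix (``needs='distance_matrix'``), declared per spec.

scikit-learn/scipy supply k-means, spectral, Gaussian mixture and
agglomerative linkage; PAM, DIANA, fuzzy c-means and the SOM partitioner are
implemented here (deterministic under the per-run seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture

__all__ = ["AlgorithmSpec", "builtin_algorithms", "AlgorithmRegistry"]

RAW, DIST = "raw_data", "distance_matrix"


@dataclass(frozen=True)
class AlgorithmSpec:
    """A pluggable base clusterer and the input it consumes."""

    name: str
    needs: Literal["raw_data", "distance_matrix"]
    fn: Callable[[np.ndarray, int, int], np.ndarray]
    metric: str | None = None  # distance metric for needs='distance_matrix'
    compatible_metrics: tuple[str, ...] = field(default_factory=tuple)

    def run(self, X: np.ndarray, k: int, seed: int) -> np.ndarray:
        labels = np.asarray(self.fn(X, k, seed), dtype=int)
        n = X.shape[0]
        if labels.shape != (n,):
            raise ValueError(f"{self.name}: expected {n} labels, got shape {labels.shape}")
        if labels.min() < 1 or labels.max() > k:
            raise ValueError(f"{self.name}: labels must lie in 1..{k}")
        return labels


# ---------------------------------------------------------------- sklearn/scipy


def _kmeans(X, k, seed):
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X) + 1


def _spectral(X, k, seed):
    n = X.shape[0]
    sc = SpectralClustering(
        n_clusters=k,
        affinity="nearest_neighbors",
        n_neighbors=min(10, n - 1),
        assign_labels="kmeans",
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # disconnected kNN graph warning is benign here
        return sc.fit_predict(X) + 1


def _gmm(X, k, seed):
    gm = GaussianMixture(n_components=k, n_init=3, reg_covar=1e-4, random_state=seed)
    return gm.fit_predict(X) + 1


def _hier(method):
    def fn(D, k, seed):
        Z = linkage(squareform(np.asarray(D), checks=False), method=method)
        return fcluster(Z, t=k, criterion="maxclust")

    return fn


# ---------------------------------------------------------------------- PAM


def _pam(D, k, seed, max_iter=100):
    """k-medoids by Voronoi iteration with a greedy BUILD initialisation."""
    D = np.asarray(D)
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new[c] = members[int(np.argmin(costs))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1) + 1


# -------------------------------------------------------------------- DIANA


def _diana(D, k, seed):
    """Divisive hierarchical clustering, cut at k clusters.

    At each step the cluster with the largest diameter is split by the
    classic splinter procedure: seed the splinter with the object of maximal
    average dissimilarity, then move objects while their average
    dissimilarity to the splinter is smaller than to the remainder.
    """
    D = np.asarray(D)
    n = D.shape[0]
    clusters = [list(range(n))]
    while len(clusters) < k:
        diams = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        i = int(np.argmax(diams))
        if diams[i] == 0.0:
            break  # only point-mass clusters left; cannot split further
        rest = clusters.pop(i)
        sub = D[np.ix_(rest, rest)]
        avg = sub.sum(axis=1) / (len(rest) - 1)
        splinter = [int(np.argmax(avg))]
        moved = True
        while moved and len(splinter) < len(rest) - 1:
            moved = False
            remain = [j for j in range(len(rest)) if j not in splinter]
            best_gain, best_j = 0.0, None
            for j in remain:
                d_spl = sub[j, splinter].mean()
                others = [m for m in remain if m != j]
                d_rem = sub[j, others].mean() if others else np.inf
                gain = d_rem - d_spl
                if gain > best_gain:
                    best_gain, best_j = gain, j
            if best_j is not None:
                splinter.append(best_j)
                moved = True
        a = [rest[j] for j in splinter]
        b = [rest[j] for j in range(len(rest)) if j not in splinter]
        clusters.extend([a, b])
    labels = np.empty(n, dtype=int)
    for idx, c in enumerate(clusters, start=1):
        labels[c] = idx
    return labels


# ------------------------------------------------------------ fuzzy c-means


def _fuzzy_cmeans(X, k, seed, m=2.0, max_iter=200, tol=1e-6):
    """Standard FCM (fuzzifier m=2), hardened by per-sample argmax."""
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)]
    u_prev = None
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        if u_prev is not None and np.abs(u - u_prev).max() < tol:
            break
        u_prev = u
    return np.argmax(u, axis=1) + 1


# ---------------------------------------------------------------------- SOM


def _som(X, k, seed, side=3, epochs=20):
    """Self-organising map followed by k-means partitioning of the codebook.

    A small ``side x side`` grid is trained online; samples map to their
    best-matching unit and units are grouped into k clusters.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_nodes = side * side
    grid = np.array([(i, j) for i in range(side) for j in range(side)], dtype=float)
    W = X[rng.choice(n, size=n_nodes, replace=True)] + 1e-6 * rng.standard_normal((n_nodes, p))
    sigma0, sigma1 = side / 2.0, 0.5
    lr0, lr1 = 0.5, 0.01
    T = epochs * n
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = t / max(T - 1, 1)
            sigma = sigma0 * (sigma1 / sigma0) ** frac
            lr = lr0 * (lr1 / lr0) ** frac
            bmu = int(np.argmin(((W - X[i]) ** 2).sum(axis=1)))
            h = np.exp(-((grid - grid[bmu]) ** 2).sum(axis=1) / (2 * sigma**2))
            W += lr * h[:, None] * (X[i] - W)
            t += 1
    proto_labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(W) + 1
    bmus = np.argmin(cdist(X, W, metric="sqeuclidean"), axis=1)
    return proto_labels[bmus]


# ------------------------------------------------------------------ registry


class AlgorithmRegistry:
    """Ordered, name-unique collection of :class:`AlgorithmSpec`."""

    def __init__(self, specs=()):
        self._specs: dict[str, AlgorithmSpec] = {}
        for s in specs:
            self.register(s)

    def register(self, spec: AlgorithmSpec) -> None:
        if spec.name in self._specs:
            raise ValueError(f"algorithm {spec.name!r} already registered")
        self._specs[spec.name] = spec

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self):
        return len(self._specs)

    def __contains__(self, name):
        return name in self._specs

    def __getitem__(self, name) -> AlgorithmSpec:
        return self._specs[name]

    def names(self) -> list[str]:
        return list(self._specs)

    def subset(self, names) -> "AlgorithmRegistry":
        return AlgorithmRegistry([self._specs[n] for n in names])


_DISTANCE_COMPAT = ("euclidean", "manhattan", "pearson_dissimilarity", "spearman_dissimilarity")


def builtin_algorithms() -> AlgorithmRegistry:
    """The default ten-algorithm registry used by the ensemble."""
    specs = [
        AlgorithmSpec("kmeans", RAW, _kmeans),
        AlgorithmSpec("pam", DIST, _pam, metric="euclidean", compatible_metrics=_DISTANCE_COMPAT),
        AlgorithmSpec("hc_average", DIST, _hier("average"), metric="euclidean", compatible_metrics=_DISTANCE_COMPAT),
        AlgorithmSpec("hc_complete", DIST, _hier("complete"), metric="euclidean", compatible_metrics=_DISTANCE_COMPAT),
        AlgorithmSpec("hc_ward", DIST, _hier("ward"), metric="euclidean", compatible_metrics=("euclidean",)),
        AlgorithmSpec("diana", DIST, _diana, metric="euclidean", compatible_metrics=_DISTANCE_COMPAT),
        AlgorithmSpec("spectral", RAW, _spectral),
        AlgorithmSpec("gmm", RAW, _gmm),
        AlgorithmSpec("fuzzy_cmeans", RAW, _fuzzy_cmeans),
        AlgorithmSpec("som", RAW, _som),
    ]
    return AlgorithmRegistry(specs)
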