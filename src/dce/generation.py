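"""Diverse cluster generation: the 4-D clustering array and its completion.

Every (algorithm, distance, k) combination is run on repeated subsamples of
80% of the observations (the default), producing an integer label array
indexed (sample, repetition, algorithm, k) with a missing marker for samples
outside a repetition's subsample. k-nearest-neighbour majority voting then
completes the array so consensus methods see a full label matrix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .algorithms import AlgorithmRegistry, AlgorithmSpec, builtin_algorithms
from .data_prep import DataMatrix, pairwise_distance

__all__ = [
    "MISSING",
    "GenerationConfig",
    "ClusteringArray",
    "builtin_algorithms",
    "subsample_indices",
    "generate_array",
    "complete_by_knn",
    "derive_seed",
]

MISSING = -1

logger = logging.getLogger("dce.generation")


def derive_seed(global_seed: int, *parts) -> int:
    """Stable 31-bit per-run seed from the global seed and run coordinates."""
    key = "|".join([str(global_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class GenerationConfig:
    """Ensemble-generation settings (algorithms, k grid, subsampling)."""

    algorithms: AlgorithmRegistry | list[AlgorithmSpec] | None = None
    k_values: tuple[int, ...] = (2, 3, 4)
    reps: int = 5
    subsample_fraction: float = 0.8
    seed: int = 0
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.algorithms is None:
            self.algorithms = builtin_algorithms()
        elif not isinstance(self.algorithms, AlgorithmRegistry):
            self.algorithms = AlgorithmRegistry(self.algorithms)
        self.k_values = tuple(int(k) for k in self.k_values)
        if not self.k_values or any(k < 2 for k in self.k_values):
            raise ValueError("k_values must be integers >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")

    def validate_against(self, n_samples: int) -> None:
        size = int(np.rint(self.subsample_fraction * n_samples))
        bad = [k for k in self.k_values if k >= size]
        if bad:
            raise ValueError(
                f"k_values {bad} not smaller than subsample size {size} "
                f"(n={n_samples}, fraction={self.subsample_fraction})"
            )


@dataclass
class ClusteringArray:
    """Labels indexed (sample, rep, algorithm, k) with provenance.

    ``labels[i, r, a, j] == MISSING`` when sample i was not in rep r's
    subsample (or the run failed: see ``failed``). ``subsamples[r]`` is the
    sorted index set drawn for rep r, shared by all algorithms and k.
    """

    labels: np.ndarray  # int array [n, reps, n_algorithms, n_k]
    sample_ids: list[str]
    algorithms: list[str]
    k_values: tuple[int, ...]
    subsamples: list[np.ndarray]
    failed: np.ndarray | None = None  # bool [reps, n_algorithms, n_k]
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.failed is None:
            self.failed = np.zeros(self.labels.shape[1:], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def reps(self) -> int:
        return self.labels.shape[1]

    def is_complete(self) -> bool:
        ok = ~self.failed
        return bool((self.labels[:, ok] != MISSING).all())

    def k_slice(self, k: int, algorithms: list[str] | None = None) -> np.ndarray:
        """Label matrix [n x runs] for one k, non-failed runs only."""
        j = self.k_values.index(k)
        a_idx = range(len(self.algorithms))
        if algorithms is not None:
            a_idx = [self.algorithms.index(a) for a in algorithms]
        cols, names = [], []
        for a in a_idx:
            for r in range(self.reps):
                if not self.failed[r, a, j]:
                    cols.append(self.labels[:, r, a, j])
                    names.append(self.algorithms[a])
        if not cols:
            raise ValueError(f"no successful runs at k={k}")
        return np.column_stack(cols), names

    def to_long_frame(self) -> pd.DataFrame:
        n, R, A, K = self.labels.shape
        idx = np.indices((n, R, A, K)).reshape(4, -1)
        return pd.DataFrame(
            {
                "sample_id": [self.sample_ids[i] for i in idx[0]],
                "rep": idx[1] + 1,
                "algorithm": [self.algorithms[a] for a in idx[2]],
                "k": [self.k_values[j] for j in idx[3]],
                "label": self.labels.reshape(-1),
            }
        )

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("failed", data=self.failed)
            f.attrs["seed"] = self.seed
            f.attrs["k_values"] = list(self.k_values)
            str_dt = h5py.string_dtype()
            f.create_dataset("sample_ids", data=np.array(self.sample_ids, dtype=object), dtype=str_dt)
            f.create_dataset("algorithms", data=np.array(self.algorithms, dtype=object), dtype=str_dt)
            g = f.create_group("subsamples")
            for r, idx in enumerate(self.subsamples):
                g.create_dataset(str(r), data=idx)

    @classmethod
    def load_hdf5(cls, path) -> "ClusteringArray":
        import h5py

        with h5py.File(path, "r") as f:
            subs = [f["subsamples"][str(r)][()] for r in range(f["labels"].shape[1])]
            return cls(
                labels=f["labels"][()],
                sample_ids=[s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][()]],
                algorithms=[s.decode() if isinstance(s, bytes) else str(s) for s in f["algorithms"][()]],
                k_values=tuple(int(k) for k in f.attrs["k_values"]),
                subsamples=subs,
                failed=f["failed"][()],
                seed=int(f.attrs["seed"]),
            )


def subsample_indices(n: int, fraction: float, reps: int, seed: int) -> list[np.ndarray]:
    """Draw ``reps`` sorted index sets of size round(fraction*n), no replacement."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    size = int(np.rint(fraction * n))
    if size < 3:
        raise ValueError(f"subsample size {size} < 3 (n={n}, fraction={fraction})")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(reps)]


def generate_array(dm: DataMatrix, cfg: GenerationConfig) -> ClusteringArray:
    """Run every (rep, algorithm, k) combination on its subsample.

    Per-run seeds derive deterministically from (cfg.seed, rep, algorithm
    name, k). A failing run is logged and its slice marked failed rather than
    aborting the ensemble.
    """
    if dm.has_missing():
        raise ValueError("prepare() the matrix before generation")
    cfg.validate_against(dm.n_samples)
    n = dm.n_samples
    algs = list(cfg.algorithms)
    subs = subsample_indices(n, cfg.subsample_fraction, cfg.reps, cfg.seed)

    # distance matrices computed once per metric actually used
    dists = {}
    for spec in algs:
        if spec.needs == "distance_matrix":
            m = spec.metric or "euclidean"
            if m not in dists:
                dists[m] = pairwise_distance(dm, m).values

    labels = np.full((n, cfg.reps, len(algs), len(cfg.k_values)), MISSING, dtype=int)
    failed = np.zeros((cfg.reps, len(algs), len(cfg.k_values)), dtype=bool)
    n_fail = 0
    for r, sub in enumerate(subs):
        for a, spec in enumerate(algs):
            if spec.needs == "distance_matrix":
                X = dists[spec.metric or "euclidean"][np.ix_(sub, sub)]
            else:
                X = dm.values[sub]
            for j, k in enumerate(cfg.k_values):
                run_seed = derive_seed(cfg.seed, r, spec.name, k)
                try:
                    labels[sub, r, a, j] = spec.run(X, k, run_seed)
                except Exception as exc:  # ensemble tolerates single-expert failure
                    failed[r, a, j] = True
                    n_fail += 1
                    logger.warning("run failed (rep=%d, algorithm=%s, k=%d): %s", r, spec.name, k, exc)
    if n_fail == failed.size:
        raise RuntimeError("all generation runs failed")
    return ClusteringArray(labels, list(dm.sample_ids), [s.name for s in algs], cfg.k_values, subs, failed, cfg.seed)


def complete_by_knn(arr: ClusteringArray, dm: DataMatrix, knn_k: int = 5) -> ClusteringArray:
    """Fill missing cells by majority vote of the knn_k nearest labelled samples.

    Neighbours are nearest by Euclidean distance in the prepared feature
    space; vote ties break to the smallest label. Failed slices stay missing.
    Completing an already complete array is the identity.
    """
    if knn_k < 1:
        raise ValueError("knn_k must be >= 1")
    labels = arr.labels.copy()
    n, R, A, K = labels.shape
    D = squareform(pdist(dm.values, metric="euclidean"))
    for r in range(R):
        sub = arr.subsamples[r]
        missing = np.setdiff1d(np.arange(n), sub)
        if missing.size == 0:
            continue
        # nearest labelled neighbours are the same for all slices of this rep
        order = np.argsort(D[np.ix_(missing, sub)], axis=1, kind="stable")[:, :knn_k]
        nbrs = sub[order]  # [n_missing, knn_k]
        for a in range(A):
            for j in range(K):
                if arr.failed[r, a, j]:
                    continue
                slice_labels = labels[:, r, a, j]
                if (slice_labels[sub] == MISSING).all():
                    raise ValueError(f"slice (rep={r}, algorithm={arr.algorithms[a]}, k={arr.k_values[j]}) has no labels")
                votes = slice_labels[nbrs]  # [n_missing, knn_k]
                kmax = arr.k_values[j]
                counts = np.zeros((missing.size, kmax + 1), dtype=int)
                for col in range(votes.shape[1]):
                    v = votes[:, col]
                    counts[np.arange(missing.size), v] += v > 0
                filled = np.argmax(counts[:, 1:], axis=1) + 1  # argmax ties -> smallest label
                labels[missing, r, a, j] = filled
    out = ClusteringArray(
        labels, list(arr.sample_ids), list(arr.algorithms), arr.k_values, [s.copy() for s in arr.subsamples], arr.failed.copy(), arr.seed
    )
    return out
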