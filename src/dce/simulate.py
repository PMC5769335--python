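"""Synthetic Gaussian-mixture and null-data generators with known truth.

These fixtures drive every test and calibration run: spherical Gaussian
blobs (optionally padded with pure-noise features) whose centres sit on a
scaled simplex so that all pairwise centre distances equal the requested
separation, and single-Gaussian null datasets for significance calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_prep import DataMatrix

__all__ = ["MixtureSpec", "simulate_mixture", "simulate_null"]


@dataclass
class MixtureSpec:
    n_per_cluster: tuple[int, ...] = (50, 50, 50)
    n_features: int = 10
    centers: np.ndarray | None = None  # explicit [k x p] centres
    separation: float = 10.0  # pairwise centre distance in units of cluster_sd
    cluster_sd: float = 1.0
    noise_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) < 1 or any(n < 1 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be positive counts")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")
        if self.centers is None and len(self.n_per_cluster) > self.n_features + 1:
            raise ValueError("simplex centres need n_features >= k - 1")


def _simplex_centers(k: int, p: int, distance: float) -> np.ndarray:
    """k points in R^p with all pairwise distances equal to ``distance``."""
    eye = np.eye(k)
    centered = (eye - eye.mean(axis=0)) * distance / np.sqrt(2.0)
    # rows of `centered` are k points with pairwise distance `distance` in R^k;
    # project onto their (k-1)-dim span, then embed in R^p
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt.T[:, : k - 1] if k > 1 else np.zeros((1, 1))
    out = np.zeros((k, p))
    out[:, : coords.shape[1]] = coords[:, :p]
    return out


def simulate_mixture(spec: MixtureSpec) -> tuple[DataMatrix, np.ndarray]:
    """Spherical Gaussian blobs plus optional standard-normal noise features.

    Returns the data matrix and true labels 1..k in generation order.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.n_per_cluster)
    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float)
        if centers.shape[0] != k:
            raise ValueError("centers must have one row per cluster")
        p_signal = centers.shape[1]
    else:
        p_signal = spec.n_features - spec.noise_features
        if p_signal < max(k - 1, 1):
            raise ValueError("not enough signal features for the requested k")
        centers = _simplex_centers(k, p_signal, spec.separation * spec.cluster_sd)
    blocks, labels = [], []
    for c, n_c in enumerate(spec.n_per_cluster):
        blocks.append(centers[c] + spec.cluster_sd * rng.standard_normal((n_c, p_signal)))
        labels.extend([c + 1] * n_c)
    X = np.vstack(blocks)
    if spec.noise_features > 0:
        X = np.hstack([X, rng.standard_normal((X.shape[0], spec.noise_features))])
    n = X.shape[0]
    dm = DataMatrix(X, [f"S{i + 1}" for i in range(n)], [f"F{j + 1}" for j in range(X.shape[1])])
    return dm, np.asarray(labels, dtype=int)


def simulate_null(n: int, p: int, covariance="isotropic", seed: int = 0) -> DataMatrix:
    """Single mean-zero Gaussian sample (isotropic or diagonal covariance)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if not (isinstance(covariance, str) and covariance == "isotropic"):
        diag = np.asarray(covariance, dtype=float)
        if diag.shape != (p,) or (diag <= 0).any():
            raise ValueError("diagonal covariance must be p positive values")
        X = X * np.sqrt(diag)
    return DataMatrix(X, [f"S{i + 1}" for i in range(n)], [f"F{j + 1}" for j in range(p)])
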