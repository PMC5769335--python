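"""Monte-Carlo significance testing of a 2-way split (SigClust-style).

The test statistic is the cluster index (CI): within-cluster sum of squares
of the best 2-way split divided by the total sum of squares. The null is a
single multivariate Gaussian whose diagonal covariance is the sample
covariance eigenvalues floored at a robust background-noise variance
estimate; the p-value is the add-one Monte-Carlo estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_prep import DataMatrix

__all__ = ["SigClustResult", "cluster_index", "estimate_null_covariance", "best_two_means", "sigclust"]

MAD_CONSTANT = 0.6745  # MAD -> sd under normality


@dataclass
class SigClustResult:
    observed_ci: float
    null_cis: np.ndarray
    p_value: float
    n_sim: int
    seed: int


def _as_array(dm) -> np.ndarray:
    return dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, dtype=float)


def cluster_index(dm, labels2: np.ndarray) -> float:
    """Within-SS over total-SS for a 2-cluster labelling (in [0, 1])."""
    X = _as_array(dm)
    labels2 = np.asarray(labels2)
    uniq = np.unique(labels2)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 non-empty clusters, got {uniq.size}")
    total = ((X - X.mean(axis=0)) ** 2).sum()
    if total <= 0:
        raise ValueError("zero total sum of squares: all points identical")
    within = sum(((X[labels2 == c] - X[labels2 == c].mean(axis=0)) ** 2).sum() for c in uniq)
    return float(within / total)


def estimate_null_covariance(dm) -> np.ndarray:
    """Eigenvalues of the null Gaussian: sample eigenvalues floored at sigma^2.

    The background noise variance sigma^2 is (MAD of all column-centred data
    values / 0.6745)^2, the robust normal-consistent estimate.
    """
    X = _as_array(dm)
    if X.shape[0] < 2:
        raise ValueError("need more than one sample")
    centered = X - X.mean(axis=0)
    flat = centered.ravel()
    mad = np.median(np.abs(flat - np.median(flat)))
    sigma2 = (mad / MAD_CONSTANT) ** 2
    cov = np.cov(X, rowvar=False)
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    return np.maximum(eig, sigma2)


def best_two_means(X: np.ndarray, restarts: int = 20, seed: int = 0, max_iter: int = 100):
    """Minimal-CI 2-means split over seeded restarts (vectorised).

    All restarts run in lockstep: centres are stored (restarts, 2, p) and
    updated until every restart's assignment is stable.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    init = np.array([rng.choice(n, size=2, replace=False) for _ in range(restarts)])
    centers = X[init]  # (r, 2, p)
    xsq = (X**2).sum(axis=1)  # (n,)

    def dists(C):
        # squared distances (r, n, 2) via one BLAS product
        prod = X @ C.reshape(restarts * 2, p).T  # (n, 2r)
        d = xsq[None, :, None] + (C**2).sum(axis=2)[:, None, :] - 2.0 * prod.reshape(n, restarts, 2).transpose(1, 0, 2)
        return d

    prev = None
    for _ in range(max_iter):
        d = dists(centers)
        assign = np.argmin(d, axis=2)  # (r, n)
        # guard against an empty side: give it the point farthest from centre 0
        empty0 = (assign == 0).sum(axis=1) == 0
        empty1 = (assign == 1).sum(axis=1) == 0
        if empty0.any() or empty1.any():
            far = np.argmax(d[:, :, 0], axis=1)
            for r in np.nonzero(empty0 | empty1)[0]:
                assign[r, far[r]] = 0 if empty0[r] else 1
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign
        mask = (assign == 1).astype(float)  # (r, n)
        s1 = mask @ X  # (r, p)
        n1 = mask.sum(axis=1)
        s_all = X.sum(axis=0)
        centers = np.stack(
            [
                (s_all[None, :] - s1) / np.maximum(n - n1, 1)[:, None],
                s1 / np.maximum(n1, 1)[:, None],
            ],
            axis=1,
        )
    total = ((X - X.mean(axis=0)) ** 2).sum()
    within = np.take_along_axis(dists(centers), assign[:, :, None], axis=2)[:, :, 0]
    # within-SS against cluster means (centres equal means at convergence)
    cis = np.maximum(within, 0.0).sum(axis=1) / total
    best = int(np.argmin(cis))
    return float(cis[best]), assign[best] + 1


def sigclust(dm, labels2: np.ndarray | None = None, n_sim: int = 1000, seed: int = 0, restarts: int = 20) -> SigClustResult:
    """Test a 2-way split against a single-Gaussian null.

    If ``labels2`` is omitted the observed split is the best seeded 2-means
    split. ``n_sim`` null datasets of the same shape are drawn from
    N(0, diag(floored eigenvalues)) and each contributes its minimal 2-means
    CI; p = (1 + #{null CI <= observed CI}) / (1 + n_sim).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    X = _as_array(dm)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if labels2 is None:
        observed_ci, _ = best_two_means(X, restarts=restarts, seed=int(rng.integers(2**31)))
    else:
        observed_ci = cluster_index(X, labels2)
    lam = estimate_null_covariance(X)
    sd = np.sqrt(lam[:p]) if lam.size >= p else np.sqrt(np.pad(lam, (0, p - lam.size)))
    null_cis = np.empty(n_sim)
    for s in range(n_sim):
        Y = rng.standard_normal((n, p)) * sd
        null_cis[s], _ = best_two_means(Y, restarts=restarts, seed=int(rng.integers(2**31)))
    p_value = (1 + int((null_cis <= observed_ci).sum())) / (1 + n_sim)
    return SigClustResult(observed_ci, null_cis, float(p_value), n_sim, seed)
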