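"""Algorithm selection: rank aggregation across validity indices, ensemble
trimming to the top performers, and evaluation-proportional weighting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evaluation import ValidityTable
from .generation import ClusteringArray

__all__ = ["TrimConfig", "rank_algorithms", "trim", "compute_weights", "weighted_consensus_matrix"]


@dataclass
class TrimConfig:
    top_n: int | None = None  # None = keep all algorithms
    reweigh: bool = False
    aggregation: str = "borda"
    mc_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation not in ("borda", "footrule_mc"):
            raise ValueError("aggregation must be 'borda' or 'footrule_mc'")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def _per_index_ranks(scores: pd.DataFrame, directions: dict[str, str]) -> dict[str, pd.Series]:
    """Average ranks per index, best = 1, NaN cells excluded."""
    ranks = {}
    for col in scores.columns:
        v = scores[col].astype(float)
        defined = v[np.isfinite(v)]
        if defined.empty:
            continue
        sign = -1.0 if directions[col] == "maximize" else 1.0
        ranks[col] = pd.Series(rankdata(sign * defined.to_numpy(), method="average"), index=defined.index)
    return ranks


def _footrule_cost(order: list[str], ranks: dict[str, pd.Series]) -> float:
    """Total Spearman footrule distance of a candidate ordering to all lists."""
    pos = {a: i + 1 for i, a in enumerate(order)}
    total = 0.0
    for r in ranks.values():
        algs = [a for a in order if a in r.index]
        cand = rankdata([pos[a] for a in algs], method="average")
        total += float(np.abs(cand - r[algs].to_numpy()).sum())
    return total


def rank_algorithms(vt: ValidityTable, cfg: TrimConfig | None = None) -> list[str]:
    """Order algorithms best-first across all validity indices.

    ``borda`` orders by mean rank over defined indices (ties alphabetical);
    ``footrule_mc`` runs a seeded Monte-Carlo search (random candidate
    orderings plus pairwise-swap hill climbing) minimising the total Spearman
    footrule distance to the per-index rank lists.
    """
    cfg = cfg or TrimConfig()
    scores = vt.best_per_algorithm()
    ranks = _per_index_ranks(scores, vt.directions)
    if not ranks:
        raise ValueError("every validity cell is undefined; cannot rank")
    mean_rank = pd.DataFrame(ranks).mean(axis=1, skipna=True)
    borda = sorted(mean_rank.index, key=lambda a: (mean_rank[a], a))
    if cfg.aggregation == "borda":
        return borda

    rng = np.random.default_rng(cfg.seed)
    best, best_cost = list(borda), _footrule_cost(borda, ranks)
    algs = list(borda)
    for _ in range(cfg.mc_samples):
        cand = list(rng.permutation(algs))
        cost = _footrule_cost(cand, ranks)
        if cost < best_cost:
            best, best_cost = cand, cost
    improved = True
    while improved:  # local pairwise-swap refinement
        improved = False
        for i, j in itertools.combinations(range(len(best)), 2):
            cand = best.copy()
            cand[i], cand[j] = cand[j], cand[i]
            cost = _footrule_cost(cand, ranks)
            if cost < best_cost:
                best, best_cost = cand, cost
                improved = True
    return best


def trim(arr: ClusteringArray, ranking: list[str], top_n: int) -> ClusteringArray:
    """Restrict the clustering array to the top_n ranked algorithms."""
    if top_n > len(ranking):
        raise ValueError(f"top_n={top_n} exceeds ranked count {len(ranking)}")
    keep = [a for a in arr.algorithms if a in set(ranking[:top_n])]
    a_idx = [arr.algorithms.index(a) for a in keep]
    return ClusteringArray(
        arr.labels[:, :, a_idx, :],
        list(arr.sample_ids),
        keep,
        arr.k_values,
        [s.copy() for s in arr.subsamples],
        arr.failed[:, a_idx, :].copy(),
        arr.seed,
    )


def compute_weights(vt: ValidityTable) -> pd.Series:
    """Algorithm weights proportional to internal evaluation scores.

    Each index column is min-max rescaled to [0, 1] (minimise-direction
    columns flipped), per-algorithm scores are the mean over defined indices,
    and weights normalise the scores to sum to 1.
    """
    scores = vt.best_per_algorithm()
    rescaled = pd.DataFrame(index=scores.index)
    for col in scores.columns:
        v = scores[col].astype(float).replace([np.inf, -np.inf], np.nan)
        if v.notna().sum() == 0:
            continue
        lo, hi = v.min(), v.max()
        s = (v - lo) / (hi - lo) if hi > lo else pd.Series(0.5, index=v.index).where(v.notna())
        rescaled[col] = 1.0 - s if vt.directions[col] == "minimize" else s
    per_alg = rescaled.mean(axis=1, skipna=True).fillna(0.0)
    total = per_alg.sum()
    if total <= 0:
        warnings.warn("all algorithm scores are zero; falling back to uniform weights")
        return pd.Series(1.0 / len(per_alg), index=per_alg.index)
    return per_alg / total


def weighted_consensus_matrix(lm: np.ndarray, run_algorithms: list[str], weights: pd.Series):
    """Co-association matrix with runs weighted by their algorithm's weight.

    Entry (i, j) = sum of weights of runs co-clustering i and j over the sum
    of weights of runs assigning both (all runs, for completed input).
    """
    from .evaluation import ConsensusMatrix
    from .generation import MISSING

    lm = np.asarray(lm, dtype=int)
    n, n_runs = lm.shape
    if len(run_algorithms) != n_runs:
        raise ValueError("need one algorithm name per run")
    missing_w = [a for a in set(run_algorithms) if a not in weights.index]
    if missing_w:
        raise ValueError(f"no weight for algorithm(s) {sorted(missing_w)}")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(n_runs):
        w = float(weights[run_algorithms[j]])
        col = lm[:, j]
        assigned = col != MISSING
        both = np.outer(assigned, assigned).astype(float) * w
        den += both
        num += both * (col[:, None] == col[None, :])
    if den.max() <= 0:
        raise ValueError("total run weight is zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(values, num, den, n_runs)
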