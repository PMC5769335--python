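"""Consensus formation: combine a completed label matrix into one partition.

Four combiners are provided: majority voting (after Hungarian label
alignment), k-modes on the categorical run-label vectors, CSPA (re-cluster
the co-association matrix) and LCE (link-based refinement of sample-cluster
associations). All are invariant to per-run label permutations and to sample
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CONSENSUS_METHODS",
    "EnsembleSolution",
    "relabel",
    "majority_vote",
    "kmodes_consensus",
    "cspa",
    "lce",
    "run_method",
]

CONSENSUS_METHODS = ("majority_voting", "kmodes", "CSPA", "LCE")


@dataclass
class EnsembleSolution:
    """A consensus partition; ``degenerate`` flags < 2 non-empty clusters."""

    method: str
    labels: np.ndarray
    k: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.degenerate = bool(self.degenerate or (self.k >= 2 and len(np.unique(self.labels)) < 2))


def _first_occurrence_relabel(labels: np.ndarray) -> np.ndarray:
    """Rename cluster IDs to 1..m in order of first appearance."""
    labels = np.asarray(labels, dtype=int)
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, v in enumerate(labels):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def relabel(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rename ``labels``'s cluster IDs to best match ``reference``.

    Solves the linear assignment problem on the contingency table (padded
    square with zeros when cluster counts differ), maximising total overlap.
    Memberships are unchanged; only IDs are renamed. Clusters matched to a
    padded reference column keep a fresh ID beyond the reference's range.
    """
    labels = np.asarray(labels, dtype=int)
    reference = np.asarray(reference, dtype=int)
    if labels.shape != reference.shape:
        raise ValueError("labels and reference must have equal length")
    k1, k2 = labels.max(), reference.max()
    m = max(k1, k2)
    cont = np.zeros((m, m), dtype=int)
    np.add.at(cont, (labels - 1, reference - 1), 1)
    rows, cols = linear_sum_assignment(-cont)
    mapping = np.zeros(m + 1, dtype=int)
    mapping[rows + 1] = cols + 1
    return mapping[labels]


def majority_vote(lm: np.ndarray, k: int, reference_run: int = 0) -> EnsembleSolution:
    """Per-sample modal label after aligning every run to a reference run.

    Vote ties break to the smallest label.
    """
    lm = np.asarray(lm, dtype=int)
    ref = lm[:, reference_run]
    aligned = np.column_stack([ref if j == reference_run else relabel(lm[:, j], ref) for j in range(lm.shape[1])])
    kmax = aligned.max()
    counts = np.zeros((lm.shape[0], kmax), dtype=int)
    for j in range(aligned.shape[1]):
        counts[np.arange(lm.shape[0]), aligned[:, j] - 1] += 1
    labels = np.argmax(counts, axis=1) + 1  # np.argmax ties -> smallest label
    return EnsembleSolution("majority_voting", labels, k)


def _kmodes_once(lm: np.ndarray, uniq: np.ndarray, k: int, pick: np.ndarray, max_iter: int):
    n, n_runs = lm.shape
    modes = uniq[pick].copy()
    kmax = int(lm.max())
    assign = None
    for _ in range(max_iter):
        # simple-matching dissimilarity sample x mode
        diss = (lm[:, None, :] != modes[None, :, :]).sum(axis=2)
        new_assign = np.argmin(diss, axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = lm[assign == c]
            if members.size == 0:
                continue  # empty cluster keeps its mode
            for pos in range(n_runs):
                counts = np.bincount(members[:, pos], minlength=kmax + 1)
                modes[c, pos] = int(np.argmax(counts[1:]) + 1)
    cost = int((lm != modes[assign]).sum())
    return assign, cost


def kmodes_consensus(lm: np.ndarray, k: int, seed: int = 0, max_iter: int = 100, restarts: int = 10) -> EnsembleSolution:
    """k-modes on the samples' run-label vectors.

    Dissimilarity is simple matching (count of disagreeing runs); modes are
    per-run majorities (ties -> smallest label); each restart is initialised
    from k distinct rows chosen by seeded draw and the lowest-cost solution
    wins. Final cluster IDs are renamed by first occurrence.

    Runs are aligned to a canonical labelling and candidate rows ordered by
    a presentation-invariant key (frequency, then the sorted profile of
    distances to all samples) before the seeded draws, so the result does
    not depend on sample order or on the runs' arbitrary cluster IDs.
    """
    lm = np.asarray(lm, dtype=int)
    n, n_runs = lm.shape
    ref = _first_occurrence_relabel(lm[:, 0])
    lm = np.column_stack([relabel(lm[:, j], ref) for j in range(n_runs)])
    uniq, inv = np.unique(lm, axis=0, return_inverse=True)
    if len(uniq) < k:
        warnings.warn(f"only {len(uniq)} distinct label vectors for k={k}; grouping identical rows")
        return EnsembleSolution("kmodes", _first_occurrence_relabel(inv + 1), k, degenerate=len(uniq) < 2)
    counts = np.bincount(inv, minlength=len(uniq))
    duu = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2)
    keys = [(-counts[i], tuple(np.sort(np.repeat(duu[i], counts)))) for i in range(len(uniq))]
    order = np.array(sorted(range(len(uniq)), key=lambda i: keys[i]))
    rng = np.random.default_rng(seed)
    best_assign, best_cost = None, None
    for _ in range(restarts):
        pick = order[rng.choice(len(uniq), size=k, replace=False)]
        assign, cost = _kmodes_once(lm, uniq, k, pick, max_iter)
        # tie-break equal costs by an order-invariant partition key
        key = tuple(sorted(np.bincount(assign, minlength=k), reverse=True))
        if best_cost is None or (cost, key) < (best_cost, best_key):
            best_assign, best_cost, best_key = assign, cost, key
    return EnsembleSolution("kmodes", _first_occurrence_relabel(best_assign + 1), k)


def _cut_average_linkage(diss: np.ndarray, k: int) -> np.ndarray:
    diss = np.asarray(diss, dtype=float)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def cspa(lm: np.ndarray, cm, k: int) -> EnsembleSolution:
    """Cluster-based similarity partitioning: cut the co-association matrix.

    Average-linkage hierarchical clustering on 1 - consensus, cut at k.
    """
    values = cm.values if hasattr(cm, "values") else np.asarray(cm, dtype=float)
    labels = _cut_average_linkage(1.0 - values, k)
    return EnsembleSolution("CSPA", _first_occurrence_relabel(labels), k)


def lce(lm: np.ndarray, k: int, dc: float = 0.8) -> EnsembleSolution:
    """Link-based cluster ensemble.

    Builds the binary sample x cluster membership matrix over all runs'
    clusters, measures cluster-cluster similarity by shared membership
    (Jaccard), refines it with the weighted connected-triple rule (similarity
    through common neighbour clusters, normalised to the maximum triple
    weight), then forms the refined association matrix: 1 where the sample
    belongs to the cluster, else ``dc`` times the refined similarity between
    that cluster and the sample's own cluster in the same run. Samples are
    partitioned by average-linkage clustering of the association rows.
    """
    if not 0 <= dc <= 1:
        raise ValueError("dc must lie in [0, 1]")
    lm = np.asarray(lm, dtype=int)
    n, n_runs = lm.shape
    cols = []
    run_of_col: list[int] = []
    own_col = np.zeros((n, n_runs), dtype=int)  # column index of sample's own cluster per run
    for j in range(n_runs):
        for lab in np.unique(lm[:, j]):
            member = lm[:, j] == lab
            own_col[member, j] = len(cols)
            cols.append(member)
            run_of_col.append(j)
    M = np.column_stack(cols).astype(float)  # n x C binary membership
    C = M.shape[1]
    inter = M.T @ M
    sizes = M.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(S, 1.0)

    if dc > 0 and C > 1:
        Sz = S.copy()
        np.fill_diagonal(Sz, 0.0)
        wct = np.zeros((C, C))
        for q in range(C):  # triple weight through common neighbour q
            wct += np.minimum.outer(Sz[:, q], Sz[:, q])
        np.fill_diagonal(wct, 0.0)
        wmax = wct.max()
        refined = wct / wmax if wmax > 0 else wct
    else:
        refined = np.zeros((C, C))

    RA = np.zeros((n, C))
    if dc > 0:
        for j in range(n_runs):
            cidx = [c for c, rj in enumerate(run_of_col) if rj == j]
            RA[:, cidx] = dc * refined[own_col[:, j]][:, cidx]
    RA[M > 0] = 1.0
    D = squareform(pdist(RA, metric="euclidean"))
    labels = _cut_average_linkage(D, k)
    return EnsembleSolution("LCE", _first_occurrence_relabel(labels), k)


def run_method(method: str, lm: np.ndarray, k: int, cm=None, seed: int = 0, dc: float = 0.8) -> EnsembleSolution:
    """Dispatch one of the four consensus methods by name."""
    if method == "majority_voting":
        return majority_vote(lm, k)
    if method == "kmodes":
        return kmodes_consensus(lm, k, seed=seed)
    if method == "CSPA":
        if cm is None:
            from .evaluation import consensus_matrix

            cm = consensus_matrix(lm)
        return cspa(lm, cm, k)
    if method == "LCE":
        return lce(lm, k, dc=dc)
    raise ValueError(f"unknown consensus method {method!r}; supported: {CONSENSUS_METHODS}")
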