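"""Consensus diagnostics and cluster validity indices.

Covers the co-association (consensus) matrix and its empirical CDF, the
relative change in area under the CDF across cluster sizes, the proportion
of ambiguous clustering (PAC) and PAC-based selection of k, plus a suite of
thirteen internal validity indices and external agreement indices (ARI, NMI,
Hungarian-matched accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as skm

from .data_prep import DataMatrix
from .generation import MISSING

__all__ = [
    "ConsensusMatrix",
    "EvaluationConfig",
    "ECDF",
    "ValidityTable",
    "consensus_matrix",
    "consensus_cdf",
    "delta_auc",
    "pac",
    "select_k",
    "internal_indices",
    "external_indices",
    "INTERNAL_INDEX_DIRECTIONS",
]


@dataclass
class EvaluationConfig:
    pac_lower: float = 0.05
    pac_upper: float = 0.95
    index_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pac_lower < self.pac_upper <= 1:
            raise ValueError("require 0 <= pac_lower < pac_upper <= 1")


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering proportions with count provenance.

    ``values[i, j] = co_count[i, j] / joint_count[i, j]``; entries whose pair
    was never jointly assigned (possible only pre-completion) are NaN and
    excluded from the CDF and PAC.
    """

    values: np.ndarray
    co_count: np.ndarray
    joint_count: np.ndarray
    n_runs: int
    sample_ids: list[str] = field(default_factory=list)

    def upper_triangle(self, defined_only: bool = True) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        v = self.values[iu]
        return v[~np.isnan(v)] if defined_only else v


def consensus_matrix(lm: np.ndarray, sample_ids: list[str] | None = None) -> ConsensusMatrix:
    """Co-association matrix of a label matrix (``MISSING`` = unassigned).

    Entry (i, j) is the number of runs clustering i and j together divided by
    the number of runs in which both were assigned; with completed input the
    denominator is the run count for every pair.
    """
    lm = np.asarray(lm, dtype=int)
    if lm.ndim == 1:
        lm = lm[:, None]
    n, n_runs = lm.shape
    if n_runs < 1:
        raise ValueError("need at least one run")
    co = np.zeros((n, n), dtype=int)
    joint = np.zeros((n, n), dtype=int)
    for j in range(n_runs):
        col = lm[:, j]
        assigned = col != MISSING
        both = np.outer(assigned, assigned)
        joint += both
        co += both & (col[:, None] == col[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(joint > 0, co / np.maximum(joint, 1), np.nan)
    np.fill_diagonal(values, 1.0)
    return ConsensusMatrix(values, co, joint, n_runs, sample_ids or [])


class ECDF:
    """Right-continuous empirical CDF over consensus-matrix entries."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError("empirical CDF needs at least one defined value")
        self.points = np.sort(values)

    def __call__(self, x):
        return np.searchsorted(self.points, x, side="right") / self.points.size

    def area(self) -> float:
        """Integral of the CDF over [0, 1] (entries live in [0, 1])."""
        return float(1.0 - self.points.mean())


def consensus_cdf(cm: ConsensusMatrix) -> ECDF:
    """CDF over the defined off-diagonal upper-triangle consensus entries."""
    if cm.values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return ECDF(cm.upper_triangle())


def delta_auc(cdfs: list[ECDF], k_values: list[int]) -> dict[int, float]:
    """Relative change in area under the consensus CDF across k.

    The smallest k reports the area itself; subsequent k report
    (A(k) - A(k_prev)) / A(k_prev). A zero previous area yields NaN.
    """
    if len(cdfs) != len(k_values) or not k_values:
        raise ValueError("need one CDF per k")
    if sorted(k_values) != list(k_values):
        raise ValueError("k_values must be sorted ascending")
    areas = [c.area() for c in cdfs]
    out = {k_values[0]: areas[0]}
    for i in range(1, len(k_values)):
        out[k_values[i]] = (areas[i] - areas[i - 1]) / areas[i - 1] if areas[i - 1] > 0 else float("nan")
    return out


def pac(cm: ConsensusMatrix, lower: float = 0.05, upper: float = 0.95) -> float:
    """Proportion of ambiguous clustering: entries strictly inside (lower, upper).

    Boundary values count as unambiguous (open interval).
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError("require 0 <= lower < upper <= 1")
    v = cm.upper_triangle()
    if v.size == 0:
        raise ValueError("no defined consensus entries")
    return float(np.mean((v > lower) & (v < upper)))


def select_k(pac_per_k: dict[int, float]) -> int:
    """Cluster size with the smallest PAC; ties go to the smallest k."""
    defined = {k: v for k, v in pac_per_k.items() if not np.isnan(v)}
    if not defined:
        raise ValueError("all PAC values undefined")
    return min(sorted(defined), key=lambda k: defined[k])


# ------------------------------------------------------ internal validity

INTERNAL_INDEX_DIRECTIONS: dict[str, str] = {
    "calinski_harabasz": "maximize",
    "dunn": "maximize",
    "pbm": "maximize",
    "tau": "maximize",
    "gamma": "maximize",
    "c_index": "minimize",
    "davies_bouldin": "minimize",
    "mcclain_rao": "minimize",
    "sd_dis": "minimize",
    "ray_turi": "minimize",
    "g_plus": "minimize",
    "silhouette": "maximize",
    "compactness": "minimize",
}


def _pair_concordance(dists: np.ndarray, within_mask: np.ndarray):
    """s+, s- and tie counts between within- and between-cluster distances."""
    w = np.sort(dists[within_mask])
    b = np.sort(dists[~within_mask])
    if w.size == 0 or b.size == 0:
        return None
    # s+ : within < between ; s- : within > between
    s_plus = int((b.size - np.searchsorted(b, w, side="right")).sum())
    s_minus = int(np.searchsorted(b, w, side="left").sum())
    return s_plus, s_minus, w, b


def internal_indices(
    dm: DataMatrix | np.ndarray, labels: np.ndarray, index_set: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Thirteen internal validity indices (standard definitions).

    Indices undefined for the input (single cluster, zero denominators)
    come back as NaN; degenerate-but-signed cases (zero diameters) as +/-inf.
    All distance-based indices use Euclidean distance on the prepared data.
    """
    X = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length must match sample count")
    names = list(index_set) if index_set else list(INTERNAL_INDEX_DIRECTIONS)
    unknown = [n for n in names if n not in INTERNAL_INDEX_DIRECTIONS]
    if unknown:
        raise ValueError(f"unknown indices {unknown}; supported: {sorted(INTERNAL_INDEX_DIRECTIONS)}")

    uniq = np.unique(labels)
    k = uniq.size
    n = X.shape[0]
    out: dict[str, float] = {}
    if k < 2:
        return {name: float("nan") for name in names}

    centroids = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    grand = X.mean(axis=0)
    cent_d = squareform(pdist(centroids))
    dvec = pdist(X)
    iu = np.triu_indices(n, k=1)
    within_mask = labels[iu[0]] == labels[iu[1]]
    conc = _pair_concordance(dvec, within_mask)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own_cent = centroids[np.searchsorted(uniq, labels)]
    wss = ((X - own_cent) ** 2).sum()
    d_to_own = np.linalg.norm(X - own_cent, axis=1)
    NT = dvec.size
    m_w = int(within_mask.sum())
    m_b = NT - m_w

    def compute(name: str) -> float:
        if name == "calinski_harabasz":
            return float(skm.calinski_harabasz_score(X, labels))
        if name == "silhouette":
            return float(skm.silhouette_score(X, labels)) if sizes.min() >= 1 and k < n else float("nan")
        if name == "davies_bouldin":
            return float(skm.davies_bouldin_score(X, labels))
        if name == "dunn":
            Dsq = squareform(dvec)
            diam = max(Dsq[np.ix_(labels == c, labels == c)].max() for c in uniq)
            inter = min(
                Dsq[np.ix_(labels == a, labels == b)].min() for ai, a in enumerate(uniq) for b in uniq[ai + 1 :]
            )
            return float(inter / diam) if diam > 0 else float("inf")
        if name == "pbm":
            e1 = float(np.linalg.norm(X - grand, axis=1).sum())
            ek = float(d_to_own.sum())
            dmax = float(cent_d.max())
            return float(((e1 * dmax) / (k * ek)) ** 2) if ek > 0 else float("inf")
        if name in ("tau", "gamma", "g_plus"):
            if conc is None:
                return float("nan")
            s_plus, s_minus, _, _ = conc
            if name == "gamma":
                tot = s_plus + s_minus
                return float((s_plus - s_minus) / tot) if tot > 0 else float("nan")
            if name == "g_plus":
                return float(2.0 * s_minus / (NT * (NT - 1)))
            nt_pairs = NT * (NT - 1) / 2.0
            ties = m_w * (m_w - 1) / 2.0 + m_b * (m_b - 1) / 2.0
            denom = np.sqrt((nt_pairs - ties) * nt_pairs)
            return float((s_plus - s_minus) / denom) if denom > 0 else float("nan")
        if name == "c_index":
            s_w = float(dvec[within_mask].sum())
            d_sorted = np.sort(dvec)
            s_min = float(d_sorted[:m_w].sum())
            s_max = float(d_sorted[-m_w:].sum()) if m_w > 0 else 0.0
            return float((s_w - s_min) / (s_max - s_min)) if s_max > s_min else float("nan")
        if name == "mcclain_rao":
            if m_w == 0 or m_b == 0:
                return float("nan")
            sw_bar = dvec[within_mask].mean()
            sb_bar = dvec[~within_mask].mean()
            return float(sw_bar / sb_bar) if sb_bar > 0 else float("inf")
        if name == "sd_dis":
            off = cent_d[np.triu_indices(k, 1)]
            if off.min() <= 0:
                return float("inf")
            dmax, dmin = off.max(), off.min()
            row_sums = cent_d.sum(axis=1)
            return float((dmax / dmin) * np.sum(1.0 / row_sums))
        if name == "ray_turi":
            min_sep = float((cent_d[np.triu_indices(k, 1)] ** 2).min())
            return float((wss / n) / min_sep) if min_sep > 0 else float("inf")
        if name == "compactness":
            return float(dvec[within_mask].mean()) if m_w > 0 else float("nan")
        raise AssertionError(name)

    for name in names:
        try:
            out[name] = compute(name)
        except Exception:
            out[name] = float("nan")
    return out


def external_indices(labels: np.ndarray, reference: np.ndarray) -> dict[str, float]:
    """Agreement with reference labels: ARI, NMI and matched accuracy.

    ARI uses the permutation-model expectation correction; NMI is normalised
    by the arithmetic mean of the entropies; accuracy is computed after
    Hungarian matching of cluster IDs to reference classes.
    """
    labels = np.asarray(labels, dtype=int)
    reference = np.asarray(reference, dtype=int)
    if labels.shape != reference.shape:
        raise ValueError("labels and reference must have equal length")
    cont = pd.crosstab(labels, reference).to_numpy()
    m = max(cont.shape)
    padded = np.zeros((m, m), dtype=int)
    padded[: cont.shape[0], : cont.shape[1]] = cont
    rows, cols = linear_sum_assignment(-padded)
    accuracy = padded[rows, cols].sum() / labels.size
    return {
        "ari": float(skm.adjusted_rand_score(reference, labels)),
        "nmi": float(skm.normalized_mutual_info_score(reference, labels, average_method="arithmetic")),
        "accuracy": float(accuracy),
    }


class ValidityTable:
    """Index scores per (algorithm-or-ensemble, k) with per-index direction."""

    def __init__(self, df: pd.DataFrame, directions: dict[str, str] | None = None):
        self.df = df
        self.directions = directions or {c: INTERNAL_INDEX_DIRECTIONS[c] for c in df.columns}
        missing = [c for c in df.columns if c not in self.directions]
        if missing:
            raise ValueError(f"no direction declared for columns {missing}")

    @classmethod
    def from_records(cls, records: list[tuple[str, int, dict[str, float]]]) -> "ValidityTable":
        idx = pd.MultiIndex.from_tuples([(a, k) for a, k, _ in records], names=["algorithm", "k"])
        df = pd.DataFrame([scores for _, _, scores in records], index=idx)
        return cls(df)

    def best_per_algorithm(self) -> pd.DataFrame:
        """Per algorithm, each index's best score across k (direction-aware)."""
        rows = {}
        for alg, sub in self.df.groupby(level="algorithm", sort=False):
            rows[alg] = {
                c: (sub[c].max() if self.directions[c] == "maximize" else sub[c].min()) for c in self.df.columns
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write("# directions," + ",".join(f"{c}={self.directions[c]}" for c in self.df.columns) + "\n")
            self.df.to_csv(f, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ValidityTable":
        with open(path) as f:
            header = f.readline().strip()
            directions = dict(part.split("=") for part in header.split(",")[1:])
            df = pd.read_csv(f, index_col=[0, 1])
        return cls(df, directions)
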