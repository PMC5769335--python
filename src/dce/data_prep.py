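"""Input matrix handling: loading, sanitising, scaling and pairwise distances.

The clustering substrate is a samples x features numeric matrix. Everything
downstream (cluster generation, completion, validity indices) assumes the
matrix returned by :func:`prepare`: fully numeric, no missing values, unique
sample and feature identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "DataMatrix",
    "DistanceMatrix",
    "load_matrix",
    "prepare",
    "pairwise_distance",
    "DISTANCE_METRICS",
    "register_metric",
]


@dataclass
class DataMatrix:
    """Samples x features matrix with row/column identifiers.

    ``values`` may contain NaN until :func:`prepare` has run; all clustering
    entry points require a prepared (NaN-free) matrix.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {p} columns")
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample-dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    metric: str
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-10).any():
            raise ValueError("distances must be nonnegative")
        self.values = np.maximum(self.values, 0.0)
        np.fill_diagonal(self.values, 0.0)


def load_matrix(path, delimiter: str = ",", has_header: bool = True) -> DataMatrix:
    """Read a delimited numeric table (first column = sample IDs).

    Empty cells become NaN (to be imputed or rejected by :func:`prepare`);
    non-numeric text cells raise a parse error naming the offending data row.
    """
    header = 0 if has_header else None
    try:
        df = pd.read_csv(path, sep=delimiter, header=header, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"non-rectangular or malformed table in {path}: {exc}") from exc
    if df.shape[0] < 3:
        raise ValueError(f"need at least 3 data rows, got {df.shape[0]}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna() & (df.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        rows = sorted({int(i) + 1 for i in np.nonzero(bad.to_numpy())[0]})
        raise ValueError(f"non-numeric cell(s) in data row(s) {rows} of {path}")
    if not has_header:
        numeric.columns = [f"V{j + 1}" for j in range(numeric.shape[1])]
    return DataMatrix(numeric.to_numpy(dtype=float), list(df.index), [str(c) for c in numeric.columns])


def prepare(
    dm: DataMatrix,
    scale: bool = False,
    top_var_features: int | None = None,
    impute_missing: bool = False,
) -> DataMatrix:
    """Sanitise a matrix ahead of cluster generation.

    Order of operations: impute (feature median) -> variance filter -> scale
    (mean 0, population sd 1; constant features dropped).
    """
    X = dm.values.copy()
    features = list(dm.feature_ids)

    if np.isnan(X).any():
        if not impute_missing:
            raise ValueError("matrix contains missing values; pass impute_missing=True or clean the input")
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            names = [features[j] for j in np.nonzero(all_missing)[0]]
            raise ValueError(f"feature(s) entirely missing: {names}")
        med = np.nanmedian(X, axis=0)
        idx = np.nonzero(np.isnan(X))
        X[idx] = med[idx[1]]

    if top_var_features is not None:
        if not 1 <= top_var_features <= X.shape[1]:
            raise ValueError(f"top_var_features={top_var_features} not in [1, {X.shape[1]}]")
        var = X.var(axis=0)
        # stable sort keeps feature order on ties
        order = np.argsort(-var, kind="stable")[:top_var_features]
        order = np.sort(order)
        X = X[:, order]
        features = [features[j] for j in order]

    if scale:
        sd = X.std(axis=0)  # population sd
        keep = sd > 0
        if not keep.all():
            import warnings

            dropped = [features[j] for j in np.nonzero(~keep)[0]]
            warnings.warn(f"dropping constant feature(s) under scaling: {dropped}")
            X = X[:, keep]
            features = [f for f, k in zip(features, keep) if k]
        if X.shape[1] == 0:
            raise ValueError("no features survive preparation")
        X = (X - X.mean(axis=0)) / X.std(axis=0)

    if X.shape[1] == 0:
        raise ValueError("no features survive preparation")
    return DataMatrix(X, list(dm.sample_ids), features)


def _correlation_dissimilarity(X: np.ndarray, rank: bool) -> np.ndarray:
    if rank:
        X = np.apply_along_axis(rankdata, 1, X)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(X)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    d = 1.0 - c
    return (d + d.T) / 2.0


DISTANCE_METRICS: dict = {
    "euclidean": lambda X: squareform(pdist(X, metric="euclidean")),
    "manhattan": lambda X: squareform(pdist(X, metric="cityblock")),
    "pearson_dissimilarity": lambda X: _correlation_dissimilarity(X, rank=False),
    "spearman_dissimilarity": lambda X: _correlation_dissimilarity(X, rank=True),
}


def register_metric(name: str, fn) -> None:
    """Add a user metric (matrix -> square dissimilarity) to the registry."""
    if name in DISTANCE_METRICS:
        raise ValueError(f"metric {name!r} already registered")
    DISTANCE_METRICS[name] = fn


def pairwise_distance(dm: DataMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample dissimilarities under a registered metric.

    Correlation dissimilarities are ``1 - r`` across features; correlation
    metrics need at least 2 features.
    """
    if dm.has_missing():
        raise ValueError("prepare() the matrix before computing distances")
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {sorted(DISTANCE_METRICS)}")
    D = DISTANCE_METRICS[metric](dm.values)
    return DistanceMatrix(D, metric, list(dm.sample_ids))
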