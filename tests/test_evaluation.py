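import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dce import (
    DataMatrix,
    consensus_cdf,
    consensus_matrix,
    delta_auc,
    external_indices,
    internal_indices,
    pac,
    select_k,
)
from dce.evaluation import INTERNAL_INDEX_DIRECTIONS, ECDF, EvaluationConfig, ValidityTable
from dce.generation import MISSING


# ------------------------------------------------------- consensus matrix


def test_consensus_matrix_unanimous_runs():
    lm = np.array([[1, 1], [1, 1], [2, 2]])
    cm = consensus_matrix(lm)
    assert cm.values[0, 1] == 1.0
    assert cm.values[0, 2] == 0.0
    assert cm.values[1, 2] == 0.0
    assert np.allclose(np.diag(cm.values), 1.0)


def test_consensus_matrix_hand_counts():
    lm = np.column_stack([[1, 1, 2], [1, 2, 2]])
    cm = consensus_matrix(lm)
    assert cm.values[0, 1] == 0.5
    assert cm.values[1, 2] == 0.5
    assert cm.values[0, 2] == 0.0


def test_consensus_matrix_single_run_binary():
    cm = consensus_matrix(np.array([[1], [2], [1], [2]]))
    off = cm.upper_triangle()
    assert set(off) <= {0.0, 1.0}


def _brute_force_consensus(lm):
    n, R = lm.shape
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            co = joint = 0
            for r in range(R):
                if lm[i, r] != MISSING and lm[j, r] != MISSING:
                    joint += 1
                    co += lm[i, r] == lm[j, r]
            if joint:
                vals[i, j] = co / joint
    np.fill_diagonal(vals, 1.0)
    return vals


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_consensus_matrix_matches_bruteforce_with_missing(seed):
    rng = np.random.default_rng(seed)
    lm = rng.integers(1, 4, size=(20, rng.integers(1, 10)))
    drop = rng.random(lm.shape) < 0.2
    lm[drop] = MISSING
    cm = consensus_matrix(lm)
    expect = _brute_force_consensus(lm)
    np.testing.assert_allclose(cm.values, expect, equal_nan=True)


# --------------------------------------------------------------- CDF / AUC


def test_cdf_point_mass():
    cdf = ECDF(np.full(6, 0.5))
    assert cdf(0.49) == 0.0
    assert cdf(0.5) == 1.0


def test_cdf_two_blocks_of_two():
    lm = np.array([[1], [1], [2], [2]])
    cdf = consensus_cdf(consensus_matrix(np.column_stack([lm, lm])))
    assert cdf(0.0) == pytest.approx(4 / 6)
    assert cdf(1.0) == 1.0


def test_auc_point_mass_at_zero():
    assert ECDF(np.zeros(5)).area() == pytest.approx(1.0)


def test_auc_two_point_masses():
    vals = np.array([0.0, 0.0, 1.0])  # mass 2/3 at 0, 1/3 at 1
    assert ECDF(vals).area() == pytest.approx(2 / 3)


def test_delta_auc_identical_cdfs():
    vals = np.array([0.1, 0.4, 0.9])
    d = delta_auc([ECDF(vals), ECDF(vals)], [2, 3])
    assert d[2] == pytest.approx(ECDF(vals).area())
    assert d[3] == pytest.approx(0.0)


# --------------------------------------------------------------------- PAC


class _FakeCM:
    def __init__(self, vals):
        self.vals = np.asarray(vals, dtype=float)

    def upper_triangle(self, defined_only=True):
        return self.vals


def test_pac_examples():
    assert pac(_FakeCM([0.0, 1.0, 1.0, 0.0]), 0.1, 0.9) == 0.0
    assert pac(_FakeCM([0.5, 0.5, 0.5]), 0.1, 0.9) == 1.0
    assert pac(_FakeCM([0.2, 0.95, 0.5, 1.0, 0.05, 0.5]), 0.1, 0.9) == pytest.approx(0.5)


def test_pac_boundary_values_unambiguous():
    assert pac(_FakeCM([0.1, 0.9]), 0.1, 0.9) == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_pac_cdf_identity(seed):
    """PAC + CDF(lower) + (1 - CDF(upper)) = 1 away from the bounds."""
    rng = np.random.default_rng(seed)
    vals = rng.random(40)
    lower, upper = 0.05, 0.95
    vals = vals[(np.abs(vals - lower) > 1e-9) & (np.abs(vals - upper) > 1e-9)]
    cm = _FakeCM(vals)
    cdf = ECDF(vals)
    assert pac(cm, lower, upper) + cdf(lower) + (1 - cdf(upper)) == pytest.approx(1.0)


def test_select_k_argmin_and_ties():
    assert select_k({2: 0.40, 3: 0.10, 4: 0.25}) == 3
    assert select_k({2: 0.10, 3: 0.10}) == 2
    assert select_k({2: 0.9}) == 2
    with pytest.raises(ValueError):
        select_k({2: float("nan")})


def test_evaluation_config_validates_bounds():
    with pytest.raises(ValueError):
        EvaluationConfig(pac_lower=0.9, pac_upper=0.1)


# ------------------------------------------------------- internal indices


def test_internal_indices_returns_thirteen(three_blobs):
    dm, truth = three_blobs
    scores = internal_indices(dm, truth)
    assert len(scores) == 13
    assert set(scores) == set(INTERNAL_INDEX_DIRECTIONS)
    assert all(np.isfinite(v) for v in scores.values())


def test_silhouette_extremes_on_tight_blobs():
    from dce import MixtureSpec, simulate_mixture

    dm, truth = simulate_mixture(
        MixtureSpec(n_per_cluster=(15, 15), n_features=3, separation=500.0, cluster_sd=1.0, seed=2)
    )
    assert internal_indices(dm, truth, index_set=("silhouette",))["silhouette"] > 0.99
    rng = np.random.default_rng(0)
    shuffled = internal_indices(dm, rng.permutation(truth), index_set=("silhouette",))
    assert shuffled["silhouette"] < 0.2


def test_internal_indices_good_vs_shuffled_labels(three_blobs):
    dm, truth = three_blobs
    good = internal_indices(dm, truth)
    rng = np.random.default_rng(0)
    shuffled = internal_indices(dm, rng.permutation(truth))
    assert shuffled["silhouette"] < 0.2
    # every index should prefer the true partition under its own direction
    for name, direction in INTERNAL_INDEX_DIRECTIONS.items():
        if direction == "maximize":
            assert good[name] > shuffled[name], name
        else:
            assert good[name] < shuffled[name], name


def test_internal_indices_single_cluster_undefined(three_blobs):
    dm, _ = three_blobs
    scores = internal_indices(dm, np.ones(dm.n_samples, dtype=int))
    assert all(np.isnan(v) for v in scores.values())


def test_dunn_degenerate_singletons():
    dm = DataMatrix(np.array([[0.0], [0.0], [5.0], [5.0]]), list("abcd"), ["x"])
    scores = internal_indices(dm, np.array([1, 1, 2, 2]))
    assert scores["dunn"] == np.inf  # zero intra-cluster diameter


def test_silhouette_matches_manual_definition():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([1, 1, 2, 2])
    dm = DataMatrix(X, list("abcd"), ["x"])
    got = internal_indices(dm, labels, index_set=("silhouette",))["silhouette"]
    # manual: a=1 for everyone; b = mean distance to other cluster
    sil = []
    for i in range(4):
        a = np.mean([abs(X[i, 0] - X[j, 0]) for j in range(4) if labels[j] == labels[i] and j != i])
        b = np.mean([abs(X[i, 0] - X[j, 0]) for j in range(4) if labels[j] != labels[i]])
        sil.append((b - a) / max(a, b))
    assert got == pytest.approx(np.mean(sil))


# ------------------------------------------------------- external indices


def test_external_indices_identity_and_permutation():
    labels = np.array([1, 1, 2, 2])
    out = external_indices(labels, labels)
    assert out == {"ari": 1.0, "nmi": 1.0, "accuracy": 1.0}
    flipped = external_indices(labels, np.array([2, 2, 1, 1]))
    assert flipped["ari"] == pytest.approx(1.0)
    assert flipped["accuracy"] == pytest.approx(1.0)


def _ari_permutation_oracle(labels, reference):
    """ARI = (R - E[R]) / (1 - E[R]) with E[R] averaged over all arrangements
    of `labels` (the permutation null keeps cluster sizes fixed)."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))

    def rand(a, b):
        agree = sum((a[i] == a[j]) == (b[i] == b[j]) for i, j in pairs)
        return agree / len(pairs)

    r_obs = rand(labels, reference)
    perms = set(itertools.permutations(labels))
    r_exp = np.mean([rand(np.array(p), reference) for p in perms])
    if r_exp == 1.0:
        return 1.0
    return (r_obs - r_exp) / (1.0 - r_exp)


@pytest.mark.parametrize(
    "labels,reference",
    [
        ([1, 1, 1, 2], [1, 1, 2, 2]),
        ([1, 2, 1, 2, 3, 3], [1, 1, 2, 2, 3, 3]),
        ([1, 1, 2, 2, 2, 3, 3], [2, 2, 1, 1, 3, 3, 3]),
    ],
)
def test_ari_matches_permutation_oracle(labels, reference):
    got = external_indices(np.array(labels), np.array(reference))["ari"]
    want = _ari_permutation_oracle(np.array(labels), np.array(reference))
    assert got == pytest.approx(want, abs=1e-10)


def test_ari_symmetric_and_near_zero_for_random_partitions():
    rng = np.random.default_rng(0)
    aris = []
    for _ in range(100):
        a = rng.integers(1, 5, size=200)
        b = rng.integers(1, 5, size=200)
        ab = external_indices(a, b)["ari"]
        assert ab == pytest.approx(external_indices(b, a)["ari"], abs=1e-12)
        aris.append(ab)
    assert abs(np.mean(aris)) < 0.05


# ---------------------------------------------------------- validity table


def test_validity_table_roundtrip(tmp_path, three_blobs):
    dm, truth = three_blobs
    vt = ValidityTable.from_records(
        [("kmeans", 3, internal_indices(dm, truth)), ("pam", 3, internal_indices(dm, truth))]
    )
    path = tmp_path / "validity.csv"
    vt.to_csv(path)
    back = ValidityTable.from_csv(path)
    assert back.directions == vt.directions
    np.testing.assert_allclose(back.df.to_numpy(), vt.df.to_numpy(), rtol=1e-9)
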