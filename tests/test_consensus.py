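import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dce import (
    consensus_matrix,
    cspa,
    external_indices,
    kmodes_consensus,
    lce,
    majority_vote,
    relabel,
)
from dce.consensus import CONSENSUS_METHODS, run_method


# ------------------------------------------------------------------ relabel


def test_relabel_pure_permutation():
    out = relabel(np.array([2, 2, 1, 1]), np.array([1, 1, 2, 2]))
    assert np.array_equal(out, [1, 1, 2, 2])


def test_relabel_identity():
    labels = np.array([1, 2, 2, 3, 1])
    assert np.array_equal(relabel(labels, labels), labels)


def test_relabel_extra_cluster_keeps_own_id():
    """Brute-force over all injective mappings confirms the assignment optimum."""
    labels = np.array([1, 1, 2, 3])
    reference = np.array([1, 1, 2, 2])
    out = relabel(labels, reference)
    assert np.array_equal(out, [1, 1, 2, 3])

    def overlap(mapped):
        return int((mapped == reference).sum())

    best = max(
        overlap(np.array([perm[l - 1] for l in labels]))
        for perm in itertools.permutations([1, 2, 3])
    )
    assert overlap(out) == best


def test_relabel_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        relabel(np.array([1, 2]), np.array([1, 2, 3]))


# ------------------------------------------------------------ majority vote


def test_majority_vote_unanimity():
    col = np.array([1, 1, 2, 2, 3])
    sol = majority_vote(np.column_stack([col, col, col]), k=3)
    assert np.array_equal(sol.labels, col)
    assert not sol.degenerate


def test_majority_vote_permuted_columns():
    base = np.array([1, 1, 2, 2])
    perms = [base, np.array([2, 2, 1, 1]), np.array([2, 2, 1, 1])]
    sol = majority_vote(np.column_stack(perms), k=2)
    assert np.array_equal(sol.labels, base)


def test_majority_vote_dissent_resolved_by_count():
    # sample 2 (index 1): votes (1, 2, 1) -> majority 1
    lm = np.array(
        [
            [1, 1, 1],
            [1, 2, 1],
            [2, 2, 2],
            [2, 2, 2],
        ]
    )
    sol = majority_vote(lm, k=2)
    assert np.array_equal(sol.labels, [1, 1, 2, 2])


# ---------------------------------------------------------------- k-modes


def _simple_matching_cost(lm, labels):
    cost = 0
    for c in np.unique(labels):
        members = lm[labels == c]
        for pos in range(lm.shape[1]):
            counts = np.bincount(members[:, pos])
            cost += members.shape[0] - counts.max()
    return cost


def test_kmodes_two_identical_groups():
    lm = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 2], [2, 2, 2]])
    sol = kmodes_consensus(lm, k=2, seed=0)
    assert np.array_equal(sol.labels, [1, 1, 2, 2])
    assert not sol.degenerate


def test_kmodes_all_rows_identical_degenerate():
    lm = np.ones((4, 3), dtype=int)
    with pytest.warns(UserWarning):
        sol = kmodes_consensus(lm, k=2, seed=0)
    assert sol.degenerate


def test_kmodes_matches_bruteforce_minimum():
    """6 samples, 2 noisy groups: k-modes reaches the exhaustive-minimum cost."""
    lm = np.array(
        [
            [1, 1, 1, 1],
            [2, 1, 1, 1],
            [1, 1, 2, 1],
            [2, 2, 2, 2],
            [1, 2, 2, 2],
            [2, 2, 1, 2],
        ]
    )
    sol = kmodes_consensus(lm, k=2, seed=3)
    best = min(
        _simple_matching_cost(lm, np.array(assign))
        for assign in itertools.product([1, 2], repeat=6)
        if len(set(assign)) == 2
    )
    assert _simple_matching_cost(lm, sol.labels) == best
    assert np.array_equal(sol.labels, [1, 1, 1, 2, 2, 2])


# -------------------------------------------------------------------- CSPA


def _block_cm(blocks, high=1.0, low=0.0):
    n = sum(blocks)
    cm = np.full((n, n), low)
    start = 0
    for b in blocks:
        cm[start : start + b, start : start + b] = high
        start += b
    np.fill_diagonal(cm, 1.0)
    return cm


def test_cspa_perfect_blocks():
    cm = _block_cm([3, 3])
    sol = cspa(None, cm, k=2)
    assert np.array_equal(sol.labels, [1, 1, 1, 2, 2, 2])


def test_cspa_all_ones_degenerate():
    sol = cspa(None, np.ones((5, 5)), k=2)
    assert sol.degenerate


def test_cspa_three_noisy_blocks_match_dendrogram_cut():
    rng = np.random.default_rng(0)
    cm = _block_cm([4, 4, 4], high=0.95, low=0.05)
    noise = rng.uniform(-0.05, 0.05, cm.shape)
    noise = (noise + noise.T) / 2
    cm = np.clip(cm + noise, 0, 1)
    np.fill_diagonal(cm, 1.0)
    sol = cspa(None, cm, k=3)
    assert np.array_equal(sol.labels, [1] * 4 + [2] * 4 + [3] * 4)


# --------------------------------------------------------------------- LCE


def test_lce_identical_runs_returns_partition():
    col = np.array([1, 1, 2, 2, 3])
    lm = np.column_stack([col] * 4)
    for dc in (0.0, 0.5, 0.8):
        sol = lce(lm, k=3, dc=dc)
        assert external_indices(sol.labels, col)["ari"] == pytest.approx(1.0)


def test_lce_dc_zero_reduces_to_binary_membership():
    rng = np.random.default_rng(2)
    lm = rng.integers(1, 3, size=(12, 5))
    sol = lce(lm, k=2, dc=0.0)
    # oracle: average-linkage on euclidean distances between binary membership rows
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    cols = [lm[:, j] == lab for j in range(5) for lab in np.unique(lm[:, j])]
    M = np.column_stack(cols).astype(float)
    expect = fcluster(linkage(pdist(M), method="average"), t=2, criterion="maxclust")
    assert external_indices(sol.labels, expect)["ari"] == pytest.approx(1.0)


def test_lce_recovers_blobs_from_noisy_runs(two_blobs):
    _, truth = two_blobs
    rng = np.random.default_rng(4)
    runs = []
    for _ in range(10):
        noisy = truth.copy()
        flip = rng.choice(len(truth), size=2, replace=False)
        noisy[flip] = 3 - noisy[flip]
        runs.append(noisy)
    sol = lce(np.column_stack(runs), k=2)
    assert external_indices(sol.labels, truth)["ari"] == pytest.approx(1.0)


def test_lce_rejects_bad_dc():
    with pytest.raises(ValueError, match="dc"):
        lce(np.ones((4, 2), dtype=int), k=2, dc=1.5)


# -------------------------------------------------------- shared invariants


def _run(method, lm, k, seed=0):
    return run_method(method, np.asarray(lm), k, seed=seed)


@pytest.mark.parametrize("method", CONSENSUS_METHODS)
def test_identical_columns_fixed_point(method):
    col = np.array([1, 1, 2, 2, 2, 1])
    lm = np.column_stack([col] * 5)
    sol = _run(method, lm, 2)
    assert external_indices(sol.labels, col)["ari"] == pytest.approx(1.0)


def _structured_lm(rng, n=18, n_runs=8, k=3):
    """Noisy label-permuted copies of one true partition (unique optimum)."""
    truth = np.repeat(np.arange(1, k + 1), n // k)
    runs = []
    for _ in range(n_runs):
        noisy = truth.copy()
        i = rng.integers(0, n)
        noisy[i] = rng.integers(1, k + 1)
        perm = np.concatenate([[0], rng.permutation(k) + 1])
        runs.append(perm[noisy])
    return np.column_stack(runs), truth


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
@pytest.mark.parametrize("method", CONSENSUS_METHODS)
def test_invariant_to_per_run_label_permutation(method, seed):
    rng = np.random.default_rng(seed)
    lm, _ = _structured_lm(rng)
    permuted = lm.copy()
    for j in range(lm.shape[1]):
        perm = np.concatenate([[0], rng.permutation(3) + 1])
        permuted[:, j] = perm[lm[:, j]]
    a = _run(method, lm, 3, seed=9)
    b = _run(method, permuted, 3, seed=9)
    assert external_indices(a.labels, b.labels)["ari"] == pytest.approx(1.0)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
@pytest.mark.parametrize("method", CONSENSUS_METHODS)
def test_invariant_to_sample_order(method, seed):
    rng = np.random.default_rng(seed)
    lm, _ = _structured_lm(rng)
    perm = rng.permutation(lm.shape[0])
    a = _run(method, lm, 3, seed=9)
    b = _run(method, lm[perm], 3, seed=9)
    assert external_indices(a.labels[perm], b.labels)["ari"] == pytest.approx(1.0)
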