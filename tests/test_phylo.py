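"""UPGMA, Fitch parsimony, tree search and bootstrap, cross-checked
against scipy hierarchical clustering and brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from snptyper.errors import UsageError
from snptyper.phylo import (
    AnnealSchedule,
    CharacterMatrix,
    SnpDistanceMatrix,
    bipartitions,
    bootstrap,
    distance_matrix,
    enumerate_topologies,
    fitch_score,
    mp_search,
    upgma,
)


# ---------------------------------------------------------------------------
# oracles


def sankoff_oracle(adj, matrix):
    """Minimum changes by exhaustive assignment of internal states,
    column by column (unit costs)."""
    leaves = [n for n in adj if isinstance(n, str)]
    internals = [n for n in adj if not isinstance(n, str)]
    row = {lab: i for i, lab in enumerate(matrix.labels)}
    edges = set()
    for u, nbs in adj.items():
        for v in nbs:
            edges.add(frozenset((u, v)))
    total = 0
    for j in range(matrix.n_columns):
        symbols = sorted({matrix.symbols[row[l]][j] for l in leaves})
        best = None
        for assignment in itertools.product(symbols, repeat=len(internals)):
            state = {n: s for n, s in zip(internals, assignment)}
            state.update({l: matrix.symbols[row[l]][j] for l in leaves})
            changes = sum(1 for e in edges if len({state[x] for x in e}) > 1)
            best = changes if best is None else min(best, changes)
        total += best
    return total


def upgma_oracle_cophenetic(D):
    """Cophenetic matrix from scipy average-linkage on the same data."""
    Z = hierarchy.linkage(squareform(np.asarray(D.d, dtype=float)), method="average")
    return squareform(hierarchy.cophenet(Z))


# ---------------------------------------------------------------------------
# distances


def test_distance_matrix_counts_differing_columns():
    D = distance_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGA"})
    assert D.value("a", "b") == 0
    assert D.value("a", "c") == 1


def test_distance_matrix_matches_recount_oracle():
    rng = np.random.default_rng(3)
    vecs = {f"s{i}": tuple(rng.choice(list("ACGTR"), size=20)) for i in range(6)}
    D = distance_matrix(vecs)
    for a, b in itertools.combinations(vecs, 2):
        assert D.value(a, b) == sum(x != y for x, y in zip(vecs[a], vecs[b]))


def test_distance_matrix_rejects_ragged_vectors():
    with pytest.raises(UsageError):
        distance_matrix({"a": "ACG", "b": "AC"})


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_two_taxa_closed_form():
    D = SnpDistanceMatrix(("a", "b"), np.array([[0, 4], [4, 0]]))
    dendro = upgma(D)
    assert dendro.root.height == 2.0
    assert dendro.cophenetic_distance("a", "b") == 4.0


def test_upgma_ultrametric_input_reconstructs_tree():
    # ((a,b):2,(c,d):2):4 in cophenetic units
    d = np.array(
        [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]], dtype=float
    )
    D = SnpDistanceMatrix(("a", "b", "c", "d"), d)
    dendro = upgma(D)
    assert dendro.cophenetic_r == pytest.approx(1.0)
    for i, a in enumerate(D.labels):
        for b in D.labels[i + 1:]:
            assert dendro.cophenetic_distance(a, b) == pytest.approx(D.value(a, b))


def test_upgma_matches_scipy_average_linkage():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = int(rng.integers(4, 8))
        # tie-free random distances so both implementations agree exactly
        vals = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)) * 1.0
        d = squareform(vals)
        D = SnpDistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        dendro = upgma(D)
        oracle = upgma_oracle_cophenetic(D)
        for i in range(n):
            for j in range(i + 1, n):
                assert dendro.cophenetic_distance(D.labels[i], D.labels[j]) == pytest.approx(
                    oracle[i, j]
                )


def test_upgma_single_taxon_rejected():
    with pytest.raises(UsageError):
        upgma(SnpDistanceMatrix(("a",), np.zeros((1, 1), dtype=int)))


# ---------------------------------------------------------------------------
# Fitch


def adj_quartet():
    # ((A1,A2),(B1,B2)) unrooted
    return {
        "A1": {0}, "A2": {0}, "B1": {1}, "B2": {1},
        0: {"A1", "A2", 1}, 1: {"B1", "B2", 0},
    }


def test_fitch_constant_column_costs_nothing():
    m = CharacterMatrix(("A1", "A2", "B1", "B2"), (("A",), ("A",), ("A",), ("A",)))
    assert fitch_score(adj_quartet(), m) == 0


def test_fitch_single_change_column():
    m = CharacterMatrix(("A1", "A2", "B1", "B2"), (("A",), ("A",), ("G",), ("G",)))
    assert fitch_score(adj_quartet(), m) == 1


def test_fitch_matches_sankoff_oracle_on_random_matrices():
    rng = np.random.default_rng(21)
    labels = tuple(f"t{i}" for i in range(6))
    for topo in itertools.islice(enumerate_topologies(labels), 0, 105, 21):
        symbols = tuple(tuple(rng.choice(list("ACGT"), size=10)) for _ in labels)
        m = CharacterMatrix(labels, symbols)
        assert fitch_score(topo, m) == sankoff_oracle(topo, m)


def test_fitch_invariant_under_leaf_relabelling():
    rng = np.random.default_rng(22)
    labels = tuple(f"t{i}" for i in range(6))
    symbols = tuple(tuple(rng.choice(list("ACGT"), size=8)) for _ in labels)
    m = CharacterMatrix(labels, symbols)
    topo = next(enumerate_topologies(labels))
    score = fitch_score(topo, m)
    perm = list(labels)[::-1]
    mapping = dict(zip(labels, perm))
    topo2 = {
        (mapping.get(k, k)): {mapping.get(v, v) for v in vs} for k, vs in topo.items()
    }
    m2 = CharacterMatrix(tuple(perm), symbols)
    assert fitch_score(topo2, m2) == score


# ---------------------------------------------------------------------------
# search


def test_enumeration_counts():
    assert sum(1 for _ in enumerate_topologies(["a", "b", "c", "d"])) == 3
    assert sum(1 for _ in enumerate_topologies(list("abcde"))) == 15
    assert sum(1 for _ in enumerate_topologies(list("abcdef"))) == 105


def test_four_taxon_anneal_equals_exhaustive():
    m = CharacterMatrix(
        ("a", "b", "c", "d"),
        (("A", "A"), ("A", "G"), ("G", "A"), ("G", "G")),
    )
    ex = mp_search(m, "exhaustive")
    an = mp_search(m, "anneal", seed=0)
    assert an.score == ex.score


def test_exhaustive_never_beaten_by_anneal():
    rng = np.random.default_rng(30)
    labels = tuple(f"t{i}" for i in range(6))
    for trial in range(3):
        symbols = tuple(tuple(rng.choice(list("ACG"), size=6)) for _ in labels)
        m = CharacterMatrix(labels, symbols)
        ex = mp_search(m, "exhaustive")
        an = mp_search(m, "anneal", seed=trial)
        assert ex.score <= an.score


def test_exhaustive_too_many_taxa_rejected():
    m = CharacterMatrix(tuple(f"t{i}" for i in range(10)), tuple(("A",) for _ in range(10)))
    with pytest.raises(UsageError):
        mp_search(m, "exhaustive")


def test_rooted_newick_contains_all_leaves():
    rng = np.random.default_rng(31)
    labels = tuple(f"t{i}" for i in range(7))
    symbols = tuple(tuple(rng.choice(list("ACGT"), size=12)) for _ in labels)
    res = mp_search(CharacterMatrix(labels, symbols), "anneal", seed=1)
    for lab in labels:
        assert lab in res.rooted_newick
    assert res.rooted_newick.endswith(";")


# ---------------------------------------------------------------------------
# bootstrap


def two_group_matrix(n_fixed=10, n_noise=2):
    """Two 4-taxon groups separated by `n_fixed` fixed columns."""
    labels = tuple(f"g1_{i}" for i in range(4)) + tuple(f"g2_{i}" for i in range(4))
    rng = np.random.default_rng(40)
    rows = []
    for i, lab in enumerate(labels):
        fixed = ("A",) * n_fixed if lab.startswith("g1") else ("G",) * n_fixed
        noise = tuple(rng.choice(list("ACGT"), size=n_noise))
        rows.append(fixed + noise)
    return CharacterMatrix(labels, tuple(rows))


def test_bootstrap_strong_branch_has_high_support():
    m = two_group_matrix()
    sched = AnnealSchedule(t0=1.0, cooling=0.85, proposals_per_temp=15)
    ref = mp_search(m, "anneal", seed=2, schedule=sched)
    support = bootstrap(m, n_reps=200, seed=7, schedule=sched, reference=ref)
    split = frozenset(f"g2_{i}" for i in range(4))
    assert split in support
    assert support[split] >= 99.0


def test_bootstrap_same_seed_identical():
    m = two_group_matrix(n_fixed=4, n_noise=4)
    sched = AnnealSchedule(t0=1.0, cooling=0.8, proposals_per_temp=10)
    s1 = bootstrap(m, n_reps=30, seed=5, schedule=sched)
    s2 = bootstrap(m, n_reps=30, seed=5, schedule=sched)
    assert s1 == s2


def test_bipartitions_of_quartet():
    bp = bipartitions(adj_quartet())
    assert bp == frozenset({frozenset({"B1", "B2"})})
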