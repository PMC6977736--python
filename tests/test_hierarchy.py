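"""Agglomeration correctness: set distances, merge sequences, invariances."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hlr.hierarchy import (LinkageHierarchy, build_hierarchy,
                           pairwise_set_distance)

ALL_COMBOS = [("single", "l1"), ("single", "l2"), ("complete", "l1"),
              ("complete", "l2"), ("ward", "l2")]


# ------------------------------------------------------------------- oracle
# Independent brute-force agglomeration: recomputes every set-to-set distance
# from raw point memberships with its own arithmetic at every step, and
# breaks ties by the lexicographically smallest (a, b) node pair.

def _oracle_set_distance(P, Q, linkage, metric):
    if linkage == "ward":
        cp, cq = P.mean(axis=0), Q.mean(axis=0)
        n, m = len(P), len(Q)
        return np.sqrt(2.0 * n * m / (n + m)) * np.sqrt(((cp - cq) ** 2).sum())
    best = None
    for p in P:
        for q in Q:
            d = np.abs(p - q).sum() if metric == "l1" else np.sqrt(((p - q) ** 2).sum())
            if best is None:
                best = d
            elif linkage == "single":
                best = min(best, d)
            else:
                best = max(best, d)
    return best


def oracle_agglomerate(X, linkage, metric):
    """Greedy agglomeration by exhaustive scan; returns (coords, heights)."""
    M = len(X)
    members = {i + 1: [i] for i in range(M)}
    coords, heights = [], []
    for step in range(M - 1):
        ids = sorted(members)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = _oracle_set_distance(X[members[a]], X[members[b]],
                                         linkage, metric)
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        members[M + step + 1] = members.pop(a) + members.pop(b)
        coords.append((a, b))
        heights.append(d)
    return np.array(coords), np.array(heights)


# ------------------------------------------------------------ set distances

@pytest.mark.parametrize("linkage,metric", ALL_COMBOS)
def test_singleton_sets_reduce_to_point_distance(linkage, metric):
    # two singletons at distance 3: all linkage formulas coincide
    assert pairwise_set_distance([[0.0]], [[3.0]], linkage, metric) == pytest.approx(3.0)


def test_complete_linkage_is_max_pairwise_l1():
    A = [[0, 0], [0, 2]]
    B = [[5, 0], [5, 2]]
    assert pairwise_set_distance(A, B, "complete", "l1") == pytest.approx(7.0)


def test_ward_distance_uses_scaled_centroid_separation():
    A = [[0, 0], [0, 2]]
    B = [[5, 0], [5, 2]]
    # centroids (0,1) and (5,1), |A|=|B|=2 -> sqrt(2*2*2/4) * 5
    assert pairwise_set_distance(A, B, "ward", "l2") == pytest.approx(np.sqrt(2) * 5)
    # non-sqrt variant scales by the full variance factor
    assert pairwise_set_distance(A, B, "ward", "l2", ward_sqrt=False) \
        == pytest.approx(2.0 * 5)


def test_set_distance_input_validation():
    with pytest.raises(ValueError, match="[Ww]ard"):
        pairwise_set_distance([[0.0]], [[1.0]], "ward", "l1")
    with pytest.raises(ValueError, match="dimension"):
        pairwise_set_distance([[0.0, 1.0]], [[1.0]], "single", "l2")
    with pytest.raises(ValueError):
        pairwise_set_distance(np.empty((0, 2)), [[1.0, 0.0]], "single", "l2")
    with pytest.raises(ValueError, match="unknown"):
        pairwise_set_distance([[0.0]], [[1.0]], "average", "l2")


# ---------------------------------------------------------- build_hierarchy

def test_forced_merge_sequence_on_the_line():
    # {0, 1, 10}: distances 1 < 9 < 10 force (1,2) then (3,4)
    h = build_hierarchy(np.array([[0.0], [1.0], [10.0]]), "single", "l2")
    assert h.M == 3
    assert h.coordinates.tolist() == [[1, 2], [3, 4]]
    assert h.nodes.tolist() == [4, 5]
    assert h.heights == pytest.approx([1.0, 9.0])


def test_duplicate_points_merge_at_height_zero():
    h = build_hierarchy(np.zeros((2, 3)), "complete", "l1")
    assert h.coordinates.tolist() == [[1, 2]]
    assert h.heights[0] == 0.0


def test_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        build_hierarchy(np.zeros((1, 2)))
    with pytest.raises(ValueError, match="finite"):
        build_hierarchy(np.array([[0.0], [np.nan]]))


def test_greedy_engine_breaks_ties_lexicographically():
    # unit square, single linkage: four pairs tie at distance 1
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    h = build_hierarchy(X, "single", "l2", engine="greedy")
    assert h.coordinates.tolist() == [[1, 2], [3, 4], [5, 6]]


@pytest.mark.parametrize("linkage,metric", ALL_COMBOS)
@pytest.mark.parametrize("engine", ["scipy", "greedy"])
def test_merge_sequence_matches_bruteforce_oracle(linkage, metric, engine, rng):
    for _ in range(8):
        M = int(rng.integers(2, 13))
        X = rng.normal(size=(M, 3))
        h = build_hierarchy(X, linkage, metric, engine=engine)
        coords, heights = oracle_agglomerate(X, linkage, metric)
        assert np.array_equal(h.coordinates, coords)
        assert h.heights == pytest.approx(heights)


def test_translation_and_scale_leave_merges_unchanged(rng):
    X = rng.normal(size=(15, 4))
    for linkage, metric in ALL_COMBOS:
        base = build_hierarchy(X, linkage, metric)
        shifted = build_hierarchy(X + 37.5, linkage, metric)
        scaled = build_hierarchy(3.0 * X, linkage, metric)
        assert np.array_equal(base.coordinates, shifted.coordinates)
        assert np.array_equal(base.coordinates, scaled.coordinates)
        # heights scale (linearly in the point scale for every linkage here)
        assert scaled.heights == pytest.approx(3.0 * base.heights)


@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 20))
def test_structural_invariants_on_random_inputs(seed, M):
    X = np.random.default_rng(seed).normal(size=(M, 2))
    h = build_hierarchy(X, "complete", "l2")
    h.validate()  # child bounds, each-child-once
    assert int(h.nodes[-1]) == 2 * M - 1
    # monotone linkage: non-decreasing heights
    assert np.all(np.diff(h.heights) >= -1e-12)


# ------------------------------------------------------------ serialization

def test_table_round_trip(rng):
    h = build_hierarchy(rng.normal(size=(9, 3)), "ward", "l2")
    t = h.to_table()
    assert list(t.columns) == ["a", "b", "node", "height"]
    h2 = LinkageHierarchy.from_table(t)
    assert np.array_equal(h.coordinates, h2.coordinates)
    assert h.heights == pytest.approx(h2.heights)


def test_linkage_matrix_round_trip(rng):
    h = build_hierarchy(rng.normal(size=(7, 2)), "complete", "l1")
    h2 = LinkageHierarchy.from_linkage_matrix(h.to_linkage_matrix())
    assert np.array_equal(h.coordinates, h2.coordinates)


def test_newick_export_parses_as_binary_tree(rng):
    import dendropy

    M = 11
    h = build_hierarchy(rng.normal(size=(M, 3)), "single", "l2")
    tree = dendropy.Tree.get(data=h.to_newick(), schema="newick")
    leaves = tree.leaf_nodes()
    assert len(leaves) == M
    assert sorted(lf.taxon.label for lf in leaves) == sorted(str(i) for i in range(1, M + 1))
    assert all(len(n.child_nodes()) in (0, 2) for n in tree)
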