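"""Thresholding, condensation, removable-edge detection, down-ranking."""

import itertools

import numpy as np
import pytest

from knocknet import (
    ConfidenceMatrix,
    EdgeRanking,
    ValidationError,
    condense,
    downrank,
    find_removable_edges,
    threshold_network,
)
from knocknet.fixtures import ffl_confidence, scc_confidence


def matrix_from_edges(n, weighted_edges):
    scores = np.zeros((n, n))
    for i, j, s in weighted_edges:
        scores[i, j] = s
    return ConfidenceMatrix(scores=scores)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx)
# ---------------------------------------------------------------------------


def brute_reachability(n, edges):
    """Transitive closure by repeated squaring of the boolean adjacency."""
    reach = [[False] * n for _ in range(n)]
    for i, j in edges:
        reach[i][j] = True
    changed = True
    while changed:
        changed = False
        for i, k, j in itertools.product(range(n), repeat=3):
            if reach[i][k] and reach[k][j] and not reach[i][j]:
                reach[i][j] = True
                changed = True
    return reach


def brute_sccs(n, edges):
    """SCC partition from pairwise mutual reachability."""
    reach = brute_reachability(n, edges)
    comp = [-1] * n
    c = 0
    for u in range(n):
        if comp[u] != -1:
            continue
        comp[u] = c
        for v in range(u + 1, n):
            if comp[v] == -1 and reach[u][v] and reach[v][u]:
                comp[v] = c
        c += 1
    return comp


def brute_removable(n, edges):
    """Removable edges by deleting the direct condensation edge and testing
    reachability — the deletion formulation of the path-length >= 2 test."""
    comp = brute_sccs(n, edges)
    n_comp = max(comp) + 1 if n else 0
    dag_edges = {
        (comp[u], comp[v]) for u, v in edges if comp[u] != comp[v]
    }
    removable = set()
    for u, v in edges:
        cu, cv = comp[u], comp[v]
        if cu == cv:
            continue
        remaining = dag_edges - {(cu, cv)}
        reach = brute_reachability(n_comp, remaining)
        if reach[cu][cv]:
            removable.add((u, v))
    return removable


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


class TestThreshold:
    def test_inclusive_filter(self):
        w = matrix_from_edges(3, [(0, 1, 5.0), (1, 2, 4.0), (0, 2, 3.0)])
        assert threshold_network(w, 3.5).edges == {(0, 1), (1, 2)}
        assert threshold_network(w, 4.0).edges == {(0, 1), (1, 2)}

    def test_zero_threshold_keeps_all_pairs(self):
        w = matrix_from_edges(3, [(0, 1, 5.0)])
        assert len(threshold_network(w, 0.0).edges) == 6

    def test_threshold_above_max_empties_network(self):
        w = matrix_from_edges(3, [(0, 1, 5.0)])
        assert threshold_network(w, 6.0).edges == set()

    def test_negative_threshold_rejected(self):
        w = matrix_from_edges(3, [(0, 1, 5.0)])
        with pytest.raises(ValidationError):
            threshold_network(w, -1.0)


class TestCondense:
    def test_two_cycle_contracts(self):
        w = matrix_from_edges(3, [(0, 1, 1.0), (1, 0, 1.0), (0, 2, 1.0)])
        cond = condense(threshold_network(w, 0.5))
        comps = {frozenset(c) for c in cond.components}
        assert comps == {frozenset({0, 1}), frozenset({2})}
        assert len(cond.dag_edges) == 1
        ab = cond.membership[0]
        assert cond.membership[1] == ab and cond.membership[2] != ab

    def test_acyclic_graph_gives_singletons(self):
        w = matrix_from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        cond = condense(threshold_network(w, 0.5))
        assert all(len(c) == 1 for c in cond.components)

    def test_complete_digraph_is_single_component(self):
        n = 4
        scores = np.ones((n, n))
        np.fill_diagonal(scores, 0.0)
        cond = condense(threshold_network(ConfidenceMatrix(scores=scores), 0.5))
        assert len(cond.components) == 1
        assert cond.dag_edges == set()
        # cross-check against pairwise-reachability oracle
        edges = {(i, j) for i in range(n) for j in range(n) if i != j}
        assert max(brute_sccs(n, edges)) == 0


class TestRemovable:
    def test_feed_forward_loop_shortcut_is_removable(self):
        net = threshold_network(ffl_confidence(), 3.0)
        assert find_removable_edges(net, condense(net)) == {(0, 2)}

    def test_two_cycle_with_spur_has_nothing_removable(self):
        w = matrix_from_edges(3, [(0, 1, 1.0), (1, 0, 1.0), (0, 2, 1.0)])
        net = threshold_network(w, 0.5)
        assert find_removable_edges(net, condense(net)) == set()

    def test_diamond_with_shortcut(self):
        # A->B->C, A->D->C, plus shortcut A->C
        w = matrix_from_edges(
            4, [(0, 1, 1.0), (1, 2, 1.0), (0, 3, 1.0), (3, 2, 1.0), (0, 2, 1.0)]
        )
        net = threshold_network(w, 0.5)
        assert find_removable_edges(net, condense(net)) == {(0, 2)}
        assert brute_removable(4, net.edges) == {(0, 2)}


class TestDownrank:
    def test_ffl_shortcut_demoted_below_chain(self):
        out = downrank(ffl_confidence(), 3.0)
        order = EdgeRanking.from_confidence(out).pairs[:3]
        assert order == [(0, 1), (1, 2), (0, 2)]

    def test_cycle_edges_never_demoted(self):
        out = downrank(scc_confidence(), 3.0)
        boosted = out.scores > 6.0  # boost = max + 1 = 7
        assert boosted[0, 1] and boosted[1, 0]  # the 2-cycle stays on top
        assert not boosted[1, 3]  # the shortcut around G2->G3->G4 drops

    def test_threshold_above_max_is_noop(self):
        w = ffl_confidence()
        out = downrank(w, 100.0)
        np.testing.assert_array_equal(out.scores, w.scores)

    def test_zero_threshold_on_complete_matrix_preserves_order(self, rng):
        n = 6
        scores = rng.random((n, n)) + 0.5
        np.fill_diagonal(scores, 0.0)
        w = ConfidenceMatrix(scores=scores)
        before = EdgeRanking.from_confidence(w).pairs
        after = EdgeRanking.from_confidence(downrank(w, 0.0)).pairs
        assert before == after

    def test_downrank_is_idempotent_on_ordering(self):
        w = ffl_confidence()
        once = downrank(w, 3.0)
        # any threshold above the boosted scores leaves the ranking alone
        twice = downrank(once, once.scores.max() + 1.0)
        assert (
            EdgeRanking.from_confidence(twice).pairs
            == EdgeRanking.from_confidence(once).pairs
        )

    def test_output_is_permutation_of_input_pairs(self, rng):
        n = 8
        scores = rng.random((n, n)) * 4
        np.fill_diagonal(scores, 0.0)
        w = ConfidenceMatrix(scores=scores)
        out = downrank(w, 2.0)
        assert sorted(EdgeRanking.from_confidence(out).pairs) == sorted(
            EdgeRanking.from_confidence(w).pairs
        )


# ---------------------------------------------------------------------------
# randomized agreement with the brute-force oracles
# ---------------------------------------------------------------------------


def random_thresholded(rng, max_nodes=12):
    n = int(rng.integers(3, max_nodes + 1))
    density = rng.uniform(0.05, 0.5)
    scores = np.where(rng.random((n, n)) < density, rng.random((n, n)) + 0.5, 0.0)
    np.fill_diagonal(scores, 0.0)
    return threshold_network(ConfidenceMatrix(scores=scores), 0.4), n


class TestOracleAgreement:
    def test_sccs_and_removable_match_brute_force(self, rng):
        for _ in range(60):
            net, n = random_thresholded(rng)
            cond = condense(net)
            comp_oracle = brute_sccs(n, net.edges)
            # same partition up to relabeling
            pairs_ours = {
                (u, v)
                for u in range(n)
                for v in range(n)
                if cond.membership[u] == cond.membership[v]
            }
            pairs_oracle = {
                (u, v)
                for u in range(n)
                for v in range(n)
                if comp_oracle[u] == comp_oracle[v]
            }
            assert pairs_ours == pairs_oracle
            assert find_removable_edges(net, cond) == brute_removable(n, net.edges)

    def test_removing_removable_edges_preserves_component_reachability(self, rng):
        for _ in range(40):
            net, n = random_thresholded(rng)
            cond = condense(net)
            removable = find_removable_edges(net, cond)
            kept = net.edges - removable
            comp = brute_sccs(n, net.edges)
            before = brute_reachability(n, net.edges)
            after = brute_reachability(n, kept)
            for u, v in itertools.product(range(n), repeat=2):
                if comp[u] != comp[v]:
                    assert before[u][v] == after[u][v]
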