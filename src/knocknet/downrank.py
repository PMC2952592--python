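"""Down-ranking of removable feed-forward edges.

A confidence matrix computed from knockouts scores the *causal influence*
network: knocking out a gene perturbs everything downstream, so indirect
targets score high too.  The true regulatory network is embedded in this
influence network and can only lose edges — adding one would claim a
causal influence the experiments never showed.

An edge u -> v is *removable* when the influence it encodes is already
explained by an alternative directed path u ~> v of length >= 2.  Edges
inside a strongly connected component (SCC) are exempt: every gene in a
cycle influences every other, and which cycle edges could be dropped
depends on deletion order, so cyclic cores are left untouched.  The test
is therefore run on the condensation (the DAG of SCCs) of the network
obtained by thresholding the confidence matrix:

1. keep edges with confidence >= t (network G1);
2. condense G1;
3. an edge is removable iff its endpoints lie in different SCCs and the
   condensation contains a path of length >= 2 between those SCCs;
4. every retained (essential) edge gets a uniform confidence boost large
   enough to outrank all non-boosted edges.

The boost preserves relative order inside the boosted and non-boosted
groups, so the output ranking is a permutation of the input pair set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datasets import ConfidenceMatrix
from .errors import ValidationError

__all__ = [
    "ThresholdedNetwork",
    "Condensation",
    "threshold_network",
    "condense",
    "find_removable_edges",
    "downrank",
]


@dataclass
class ThresholdedNetwork:
    """Directed network of confidence entries >= ``threshold`` (the G1
    network of the two-step algorithm)."""

    base: ConfidenceMatrix
    threshold: float
    edges: set[tuple[int, int]]

    @property
    def n_genes(self) -> int:
        return self.base.n_genes

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_genes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class Condensation:
    """SCC partition of a thresholded network and the acyclic component
    graph it induces."""

    components: list[frozenset[int]]
    membership: np.ndarray  # gene index -> component index
    dag: nx.DiGraph  # nodes = component indices

    @property
    def dag_edges(self) -> set[tuple[int, int]]:
        return set(self.dag.edges())


def threshold_network(w: ConfidenceMatrix, t: float) -> ThresholdedNetwork:
    """Keep every ordered pair with confidence >= ``t`` (inclusive, so
    ``t=0`` keeps all N(N-1) pairs of a positive matrix)."""
    if t < 0:
        raise ValidationError(f"threshold must be non-negative, got {t}")
    rows, cols = np.nonzero(w.scores >= t)
    edges = {(int(i), int(j)) for i, j in zip(rows, cols) if i != j}
    return ThresholdedNetwork(base=w, threshold=float(t), edges=edges)


def condense(net: ThresholdedNetwork) -> Condensation:
    """Contract each strongly connected component to a single vertex."""
    g = net.to_digraph()
    cond = nx.condensation(g)  # DAG; node attr "members" holds gene sets
    membership = np.empty(net.n_genes, dtype=int)
    components: list[frozenset[int]] = []
    for c in cond.nodes:
        members = frozenset(cond.nodes[c]["members"])
        components.append(members)
        for gene in members:
            membership[gene] = c
    return Condensation(components=components, membership=membership, dag=cond)


def find_removable_edges(
    net: ThresholdedNetwork, cond: Condensation
) -> set[tuple[int, int]]:
    """Gene-level edges whose causal influence survives their deletion.

    An edge (u, v) is removable iff component(u) != component(v) and the
    condensation has a directed path of >= 2 edges from component(u) to
    component(v) — equivalently, some successor m != component(v) of
    component(u) still reaches component(v).  Within-component edges are
    never returned.
    """
    dag = cond.dag
    member = cond.membership
    # component pairs that actually carry gene edges
    cross = {
        (int(member[u]), int(member[v]))
        for u, v in net.edges
        if member[u] != member[v]
    }
    desc: dict[int, set[int]] = {}

    def descendants(c: int) -> set[int]:
        if c not in desc:
            desc[c] = nx.descendants(dag, c)
        return desc[c]

    removable_pairs = set()
    for ca, cb in cross:
        for m in dag.successors(ca):
            if m != cb and cb in descendants(m):
                removable_pairs.add((ca, cb))
                break
    return {
        (u, v)
        for u, v in net.edges
        if member[u] != member[v]
        and (int(member[u]), int(member[v])) in removable_pairs
    }


def downrank(w: ConfidenceMatrix, t: float) -> ConfidenceMatrix:
    """Boost every essential thresholded edge above all others.

    Edges of the thresholded network that are *not* removable gain a
    uniform boost of ``max(w) + 1``; removable and sub-threshold pairs keep
    their original confidence.  Order is preserved within each group and
    every boosted edge outranks every non-boosted edge.
    """
    if t < 0:
        raise ValidationError(f"threshold must be non-negative, got {t}")
    net = threshold_network(w, t)
    cond = condense(net)
    removable = find_removable_edges(net, cond)
    boost = float(w.scores.max()) + 1.0
    scores = w.scores.copy()
    for u, v in net.edges - removable:
        scores[u, v] += boost
    return ConfidenceMatrix(
        scores=scores, method_tag="downranked", gene_names=list(w.gene_names)
    )
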