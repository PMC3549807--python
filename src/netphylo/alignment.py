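"""Multi-species alignment graph and star-restricted spectral clustering.

All pairwise similarity tables are merged into one k-partite graph over the
enzymes of every organism (cross-organism edges only).  Clusters of
functionally similar enzymes are then peeled off deterministically:

1. pick the unassigned member with the largest total incident weight as the
   pivot (ties break lexicographically on (organism, node));
2. form the star of the pivot and its unassigned neighbors;
3. rank the star by personalized PageRank restarted at the pivot;
4. keep the pivot plus members whose stationary mass reaches
   ``keep_ratio`` times the pivot's own mass;
5. mark the cluster assigned and repeat until no edges remain among
   unassigned members; leftover enzymes become singleton clusters.

Every free choice (pivot order, tie-breaks, PageRank tolerance) is pinned, so
identical inputs always yield the identical cluster list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .network import Member, MetabolicNetwork, NodePairScores, ValidationError

_PPR_TOL = 1e-12


@dataclass
class EnzymeCluster:
    """A set of enzymes, drawn from one or more organisms, treated as one
    conserved function.  ``entropy`` is attached by the filtering stage."""

    cluster_id: int
    members: frozenset[Member]
    entropy: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("empty cluster")
        self.members = frozenset(self.members)

    @property
    def organisms(self) -> frozenset[str]:
        return frozenset(org for org, _ in self.members)


@dataclass(frozen=True)
class ClusterParams:
    """Knobs of the star/PageRank extraction.

    damping:
        Personalized-PageRank damping factor (probability of following an
        edge rather than restarting at the pivot).
    keep_ratio:
        A star member joins the cluster when its stationary mass is at least
        ``keep_ratio`` times the pivot's mass.
    min_weight:
        Edge inclusion floor for the alignment graph; ``None`` means one
        order of magnitude below the maximum pairwise score (0.1 x max).
        Converged similarities are bimodal — background prior mass against
        true functional matches — and a relative floor keeps the stars
        dominated by signal.
    """

    damping: float = 0.85
    keep_ratio: float = 0.3
    min_weight: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValidationError("damping must be in (0,1)")
        if not 0.0 < self.keep_ratio <= 1.0:
            raise ValidationError("keep_ratio must be in (0,1]")


@dataclass
class AlignmentGraph:
    """K-partite weighted graph over all enzymes of all organisms."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def members(self) -> list[Member]:
        return sorted(self.graph.nodes)


def build_alignment_graph(
    score_tables: Iterable[NodePairScores],
    networks: Mapping[str, MetabolicNetwork],
    min_weight: float | None = None,
) -> AlignmentGraph:
    """Merge pairwise score tables into the alignment graph.

    Nodes are every enzyme of every network (so enzymes absent from all score
    tables still surface as singleton clusters); an edge joins two enzymes of
    different organisms whenever their score reaches ``min_weight``.
    """
    tables = list(score_tables)
    if min_weight is None:
        top = max(
            (s for t in tables for *_, s in t.canonical_items()), default=0.0
        )
        min_weight = 0.1 * top
    g = nx.Graph()
    for org, net in networks.items():
        for nid in net.enzyme_ids():
            g.add_node((org, nid))
    for table in tables:
        for oa, na, ob, nb, s in table.canonical_items():
            u, v = (oa, na), (ob, nb)
            if u not in g or v not in g:  # metabolite or unknown: skip
                continue
            if oa == ob or s < min_weight or s <= 0.0:
                continue
            if g.has_edge(u, v) and g.edges[u, v]["weight"] != s:
                raise ValidationError(f"conflicting weights for {u}-{v}")
            g.add_edge(u, v, weight=s)
    return AlignmentGraph(g)


def _personalized_pagerank(
    nodes: list[Member],
    weights: np.ndarray,
    pivot_index: int,
    damping: float,
) -> np.ndarray:
    """Stationary distribution of a restart-at-pivot random walk.

    ``weights`` is the symmetric weighted adjacency of the star subgraph.
    Iterated to an L1 tolerance of 1e-12; columns with zero weight (cannot
    happen inside a star, kept for safety) dangle back to the pivot.
    """
    n = len(nodes)
    col_sums = weights.sum(axis=0)
    trans = np.divide(
        weights, col_sums[None, :], out=np.zeros_like(weights), where=col_sums > 0
    )
    restart = np.zeros(n)
    restart[pivot_index] = 1.0
    x = restart.copy()
    for _ in range(10000):
        dangling = x[col_sums == 0].sum()
        x_new = damping * (trans @ x) + (1.0 - damping) * restart
        x_new[pivot_index] += damping * dangling
        if np.abs(x_new - x).sum() <= _PPR_TOL:
            x = x_new
            break
        x = x_new
    return x


def spectral_star_clusters(
    graph: AlignmentGraph, params: ClusterParams = ClusterParams()
) -> list[EnzymeCluster]:
    """Extract disjoint enzyme clusters from the alignment graph.

    Deterministic; returns clusters numbered in extraction order, singleton
    clusters (sorted lexicographically) last.
    """
    g = graph.graph
    unassigned: set[Member] = set(g.nodes)
    clusters: list[EnzymeCluster] = []
    cluster_id = 1

    def live_weight(m: Member) -> float:
        return sum(
            d["weight"] for nbr, d in g.adj[m].items() if nbr in unassigned
        )

    while True:
        candidates = [
            m
            for m in unassigned
            if any(nbr in unassigned for nbr in g.adj[m])
        ]
        if not candidates:
            break
        lw = {m: live_weight(m) for m in candidates}
        best_w = max(lw.values())
        pivot = min(m for m in candidates if lw[m] == best_w)

        star = [pivot] + sorted(
            nbr for nbr in g.adj[pivot] if nbr in unassigned
        )
        idx = {m: i for i, m in enumerate(star)}
        w = np.zeros((len(star), len(star)))
        for i, u in enumerate(star):
            for vtx, d in g.adj[u].items():
                j = idx.get(vtx)
                if j is not None:
                    w[i, j] = d["weight"]
        mass = _personalized_pagerank(star, w, 0, params.damping)
        keep = {
            star[i]
            for i in range(len(star))
            if mass[i] >= params.keep_ratio * mass[0]
        }
        keep.add(pivot)
        clusters.append(EnzymeCluster(cluster_id, frozenset(keep)))
        cluster_id += 1
        unassigned -= keep

    for m in sorted(unassigned):
        clusters.append(EnzymeCluster(cluster_id, frozenset({m})))
        cluster_id += 1
    return clusters
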