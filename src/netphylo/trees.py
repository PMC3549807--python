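"""Distance-based tree reconstruction and topology comparison.

Neighbor joining (Saitou-Nei) is the default tree builder: it is consistent
on additive matrices — distances exactly realizable as path lengths on a
weighted tree — and is the conventional choice for a whole-matrix distance
of this kind.  UPGMA is offered as an alternative for a rooted, ultrametric
view.  Trees are dendropy objects; Newick serialization writes branch
lengths at six decimals, and Robinson-Foulds counts bipartitions present in
exactly one of two unrooted trees (0 means identical topology).

Determinism: NJ ties on the Q-criterion break on the lexicographically
smaller pair of subtree representatives (the smallest leaf label each side),
so identical matrices always yield byte-identical Newick output.  Negative
NJ branch lengths are clamped to zero with a logged note.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .distance import DistanceMatrix
from .network import ValidationError

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    pass


def _validated(dm: DistanceMatrix) -> np.ndarray:
    d = np.asarray(dm.values, dtype=float)
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix not symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix diagonal not zero")
    return d


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    n = 1 gives a single leaf, n = 2 a single edge carrying the full
    distance; for n >= 3 the usual Q-criterion agglomeration runs with
    deterministic tie-breaking.
    """
    d = _validated(dm)
    labels = list(dm.organism_ids)
    ns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    if len(labels) == 1:
        tree.seed_node = nodes[0]
        return tree

    # active clusters: index -> (node, representative label)
    active = list(range(len(labels)))
    reps = {i: labels[i] for i in active}
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in active
        for j in active
        if i < j
    }
    node_of = {i: nodes[i] for i in active}
    next_id = len(labels)

    def dget(i: int, j: int) -> float:
        return dist[frozenset((i, j))]

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("negative branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        n = len(active)
        r = {i: sum(dget(i, k) for k in active if k != i) for i in active}
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * dget(i, j) - r[i] - r[j]
                ra, rb = sorted((reps[i], reps[j]))
                key = (q, ra, rb, i, j)
                if best is None or key < best:
                    best = key
        assert best is not None
        _, _, _, i, j = best
        dij = dget(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        parent = dendropy.Node()
        ci, cj = node_of[i], node_of[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = clamp(li)
        cj.edge.length = clamp(lj)
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((new, k))] = 0.5 * (dget(i, k) + dget(j, k) - dij)
        node_of[new] = parent
        reps[new] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    dij = dget(i, j)
    ci, cj = node_of[i], node_of[j]
    if ci.is_leaf() and cj.is_leaf():
        # n == 2: single edge, rendered as a two-child root
        root = dendropy.Node()
        root.add_child(ci)
        ci.edge.length = 0.0
        root.add_child(cj)
        cj.edge.length = clamp(dij)
    else:
        # attach the remaining cluster onto the internal one: the final
        # edge carries the whole residual distance, preserving path lengths
        root, other = (ci, cj) if not ci.is_leaf() else (cj, ci)
        other.edge.length = clamp(dij)
        root.add_child(other)
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) rooted ultrametric tree."""
    d = _validated(dm)
    labels = list(dm.organism_ids)
    ns = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    node_of = {
        i: dendropy.Node(taxon=ns.get_taxon(lab)) for i, lab in enumerate(labels)
    }
    height = {i: 0.0 for i in node_of}
    size = {i: 1 for i in node_of}
    reps = {i: labels[i] for i in node_of}
    active = list(node_of)
    dist = {
        frozenset((i, j)): float(d[i, j])
        for i in active
        for j in active
        if i < j
    }
    next_id = len(labels)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                ra, rb = sorted((reps[i], reps[j]))
                key = (dist[frozenset((i, j))], ra, rb, i, j)
                if best is None or key < best:
                    best = key
        dij, _, _, i, j = best  # type: ignore[misc]
        h = dij / 2.0
        parent = dendropy.Node()
        for k in (i, j):
            child = node_of[k]
            parent.add_child(child)
            child.edge.length = max(h - height[k], 0.0)
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((new, k))] = (
                size[i] * dist[frozenset((i, k))]
                + size[j] * dist[frozenset((j, k))]
            ) / (size[i] + size[j])
        node_of[new] = parent
        height[new] = h
        size[new] = size[i] + size[j]
        reps[new] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [new]
    tree.seed_node = node_of[active[0]]
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at six decimals, ending in ';'."""
    txt = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        suppress_leaf_node_labels=False,
    ).strip()
    return txt


def from_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; malformed input raises NewickParseError."""
    if text.count("(") != text.count(")"):
        opens = 0
        pos = 0
        for k, c in enumerate(text):
            if c == "(":
                opens += 1
            elif c == ")":
                opens -= 1
            if opens < 0:
                pos = k
                break
        else:
            pos = len(text)
        raise NewickParseError(
            f"unbalanced parentheses near position {pos}"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(str(exc)) from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n", encoding="utf-8")


def read_newick(path: str | Path) -> dendropy.Tree:
    return from_newick(Path(path).read_text(encoding="utf-8"))


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted symmetric-difference (RF) distance between two trees.

    Both trees must carry exactly the same leaf labels; the mismatch error
    lists the differing labels.
    """
    labels1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    labels2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValidationError(
            f"leaf sets differ: only-in-first={sorted(labels1 - labels2)}, "
            f"only-in-second={sorted(labels2 - labels1)}"
        )
    ns = dendropy.TaxonNamespace(sorted(labels1))
    a = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=ns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a weighted tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return DistanceMatrix(labels, vals)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    return tree
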