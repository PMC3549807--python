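"""Domain types and on-disk formats for metabolic networks.

A metabolic network is an undirected graph in which enzymes and metabolites
are nodes and the reactions catalyzed by enzymes are edges.  Enzyme nodes may
carry a KEGG-style functional group label (a KO or EC identifier) and a set of
pathway map identifiers; metabolite nodes carry a compound identifier.

All on-disk formats are plain tab-separated text:

* ``nodes.tsv`` — columns ``node_id, kind, group_id, pathway_ids, compound_id``
  (pathway ids semicolon-joined; empty fields mean "absent").
* ``edges.tsv`` — two node-id columns per line.
* ``scores.tsv`` — five columns ``orgA, nodeA, orgB, nodeB, score`` giving a
  sparse cross-species node-similarity prior.
* ``clusters.tsv`` — one cluster per line, members as ``organism|node`` tokens.

Writers emit canonically sorted output so that equal in-memory objects always
produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates the format."""


Member = tuple[str, str]  # (organism_id, node_id)


@dataclass(frozen=True)
class NodeRecord:
    """One node of a metabolic network.

    Parameters
    ----------
    node_id:
        Identifier, unique within its organism; no whitespace allowed.
    organism_id:
        Owning organism (KEGG three-letter codes in examples, any string).
    node_kind:
        ``"enzyme"`` or ``"metabolite"``.
    group_id:
        KEGG functional group (KO/EC) label; enzymes only, optional.
    pathway_ids:
        KEGG pathway map identifiers (e.g. ``ko00010``); enzymes only.
    compound_id:
        KEGG compound identifier; metabolites only, optional.
    """

    node_id: str
    organism_id: str
    node_kind: str
    group_id: str | None = None
    pathway_ids: frozenset[str] = frozenset()
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if self.node_kind not in ("enzyme", "metabolite"):
            raise ValidationError(
                f"node {self.node_id!r}: unknown kind {self.node_kind!r}"
            )
        if any(c.isspace() for c in self.node_id) or not self.node_id:
            raise ValidationError(f"invalid node_id {self.node_id!r}")
        if self.node_kind == "metabolite" and self.group_id is not None:
            raise ValidationError(
                f"metabolite {self.node_id!r} must not carry a group_id"
            )
        if self.node_kind == "enzyme" and self.compound_id is not None:
            raise ValidationError(
                f"enzyme {self.node_id!r} must not carry a compound_id"
            )
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))


@dataclass
class MetabolicNetwork:
    """One organism's metabolic network: typed nodes plus undirected edges.

    Edges are stored as a deduplicated set of sorted node-id pairs; self-loops
    are rejected.  ``require_enzyme`` enforces the at-least-one-enzyme
    invariant (relaxed by the simulator for saturated gene-loss regimes).
    """

    organism_id: str
    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __init__(
        self,
        organism_id: str,
        nodes: Iterable[NodeRecord] = (),
        edges: Iterable[tuple[str, str]] = (),
        require_enzyme: bool = True,
    ) -> None:
        self.organism_id = organism_id
        self.nodes = {}
        for rec in nodes:
            if rec.node_id in self.nodes:
                raise ValidationError(
                    f"{organism_id}: duplicate node_id {rec.node_id!r}"
                )
            if rec.organism_id != organism_id:
                raise ValidationError(
                    f"node {rec.node_id!r} belongs to {rec.organism_id!r}, "
                    f"not {organism_id!r}"
                )
            self.nodes[rec.node_id] = rec
        self.edges = set()
        for a, b in edges:
            if a == b:
                raise ValidationError(f"{organism_id}: self-loop on {a!r}")
            for end in (a, b):
                if end not in self.nodes:
                    raise ValidationError(
                        f"{organism_id}: edge references unknown node {end!r}"
                    )
            self.edges.add((a, b) if a <= b else (b, a))
        if require_enzyme and not any(
            r.node_kind == "enzyme" for r in self.nodes.values()
        ):
            raise ValidationError(f"{organism_id}: no enzyme node present")

    def enzyme_ids(self) -> list[str]:
        return sorted(
            nid for nid, r in self.nodes.items() if r.node_kind == "enzyme"
        )

    def metabolite_ids(self) -> list[str]:
        return sorted(
            nid for nid, r in self.nodes.items() if r.node_kind == "metabolite"
        )

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {nid: set() for nid in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.organism_id == other.organism_id
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


class NodePairScores:
    """Sparse cross-species node-to-node similarity table.

    Holds both the sequence-similarity prior fed into the alignment core and
    the converged similarity it produces.  Entries are symmetric: setting
    ``(orgA, a, orgB, b)`` makes ``(orgB, b, orgA, a)`` visible too.  Scores
    are finite and non-negative; both endpoints must name distinct organisms.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, str, str], float] = {}

    @staticmethod
    def _canon(
        org_a: str, node_a: str, org_b: str, node_b: str
    ) -> tuple[str, str, str, str]:
        if (org_a, node_a) <= (org_b, node_b):
            return (org_a, node_a, org_b, node_b)
        return (org_b, node_b, org_a, node_a)

    def set(
        self, org_a: str, node_a: str, org_b: str, node_b: str, score: float
    ) -> None:
        if org_a == org_b:
            raise ValidationError(
                f"score endpoints must be in distinct organisms: {org_a!r}"
            )
        score = float(score)
        if not math.isfinite(score) or score < 0:
            raise ValidationError(f"invalid score {score!r}")
        key = self._canon(org_a, node_a, org_b, node_b)
        prev = self._entries.get(key)
        if prev is not None and prev != score:
            raise ValidationError(
                f"conflicting scores for pair {key}: {prev} vs {score}"
            )
        self._entries[key] = score

    def get(
        self, org_a: str, node_a: str, org_b: str, node_b: str, default: float = 0.0
    ) -> float:
        return self._entries.get(
            self._canon(org_a, node_a, org_b, node_b), default
        )

    def items(self) -> Iterator[tuple[str, str, str, str, float]]:
        """Iterate entries in both orientations, canonical key first."""
        for (oa, na, ob, nb), s in self._entries.items():
            yield (oa, na, ob, nb, s)
            yield (ob, nb, oa, na, s)

    def canonical_items(self) -> list[tuple[str, str, str, str, float]]:
        return sorted((k + (v,)) for k, v in self._entries.items())

    def organisms(self) -> set[str]:
        orgs: set[str] = set()
        for oa, _, ob, _ in self._entries:
            orgs.add(oa)
            orgs.add(ob)
        return orgs

    def __len__(self) -> int:
        return len(self._entries)

    def __bool__(self) -> bool:
        return bool(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodePairScores):
            return NotImplemented
        return self._entries == other._entries


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ("node_id", "kind", "group_id", "pathway_ids", "compound_id")


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_network(
    nodes_path: str | Path, edges_path: str | Path, organism_id: str
) -> MetabolicNetwork:
    """Read one organism's network from a nodes TSV and an edges TSV.

    Blank lines and ``#`` comments are skipped; columns beyond the known
    header set are ignored.  Duplicate edges collapse; an edge naming an
    unknown node is a :class:`ValidationError`.
    """
    nodes_path, edges_path = Path(nodes_path), Path(edges_path)
    records: list[NodeRecord] = []
    header: dict[str, int] | None = None
    for lineno, line in _data_lines(nodes_path):
        cells = line.split("\t")
        if header is None:
            header = {name: i for i, name in enumerate(cells)}
            missing = [c for c in ("node_id", "kind") if c not in header]
            if missing:
                raise ValidationError(
                    f"{nodes_path}: header missing column(s) {missing}"
                )
            continue

        def cell(col: str) -> str:
            idx = header.get(col)  # type: ignore[union-attr]
            if idx is None or idx >= len(cells):
                return ""
            return cells[idx].strip()

        pathway_raw = cell("pathway_ids")
        pathways = frozenset(p for p in pathway_raw.split(";") if p)
        try:
            records.append(
                NodeRecord(
                    node_id=cell("node_id"),
                    organism_id=organism_id,
                    node_kind=cell("kind"),
                    group_id=cell("group_id") or None,
                    pathway_ids=pathways,
                    compound_id=cell("compound_id") or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{nodes_path}:{lineno}: {exc}") from exc

    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(edges_path):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 2:
            raise ValidationError(
                f"{edges_path}:{lineno}: expected two node ids, got {line!r}"
            )
        edges.append((cells[0], cells[1]))
    return MetabolicNetwork(organism_id, records, edges)


def write_network(
    net: MetabolicNetwork, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Write a network in the nodes/edges TSV dialect, canonically sorted."""
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NODE_COLUMNS) + "\n")
        for nid in sorted(net.nodes):
            rec = net.nodes[nid]
            fh.write(
                "\t".join(
                    (
                        rec.node_id,
                        rec.node_kind,
                        rec.group_id or "",
                        ";".join(sorted(rec.pathway_ids)),
                        rec.compound_id or "",
                    )
                )
                + "\n"
            )
    with open(edges_path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_scores(path: str | Path) -> NodePairScores:
    """Read a five-column score table; symmetric closure is implicit.

    The same pair listed twice with different scores is a conflict (error
    with the offending line number); an empty file yields an empty table and
    downstream code falls back to a uniform prior.
    """
    path = Path(path)
    scores = NodePairScores()
    for lineno, line in _data_lines(path):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != 5:
            raise ValidationError(
                f"{path}:{lineno}: expected 5 columns, got {len(cells)}"
            )
        oa, na, ob, nb, raw = cells
        try:
            score = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: non-numeric score {raw!r}"
            ) from None
        try:
            scores.set(oa, na, ob, nb, score)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return scores


def write_scores(scores: NodePairScores, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for oa, na, ob, nb, s in scores.canonical_items():
            fh.write(f"{oa}\t{na}\t{ob}\t{nb}\t{s:.12g}\n")


def read_clusters(path: str | Path) -> list[set[Member]]:
    """Read clusters, one per line, members as ``organism|node`` tokens.

    A trailing tab-separated numeric field (the entropy column appended by the
    filtering stage) is ignored on read.
    """
    path = Path(path)
    clusters: list[set[Member]] = []
    for lineno, line in _data_lines(path):
        members: set[Member] = set()
        for token in line.split("\t"):
            token = token.strip()
            if not token:
                continue
            if "|" not in token:
                try:
                    float(token)  # entropy column
                    continue
                except ValueError:
                    pass
                raise ValidationError(
                    f"{path}:{lineno}: malformed member token {token!r}"
                )
            org, _, node = token.partition("|")
            members.add((org, node))
        if members:
            clusters.append(members)
    return clusters


def write_clusters(
    clusters: Iterable[Iterable[Member]],
    path: str | Path,
    entropies: Mapping[int, float] | None = None,
) -> None:
    """Write clusters canonically (sorted members, sorted lines).

    ``entropies`` optionally maps the cluster's position in ``clusters`` to an
    entropy value appended as a final column.
    """
    rows: list[tuple[str, str]] = []
    for idx, members in enumerate(clusters):
        toks = sorted(f"{org}|{node}" for org, node in members)
        suffix = ""
        if entropies is not None and idx in entropies:
            suffix = f"\t{entropies[idx]:.6f}"
        rows.append(("\t".join(toks), suffix))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for body, suffix in rows:
            fh.write(body + suffix + "\n")
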