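import itertools

import numpy as np
import pytest

from netphylo import EnzymeCluster, MetabolicNetwork, NodeRecord


def make_enzyme_net(org, enzymes, metabolites=(), edges=()):
    """Build a small network; ``enzymes`` maps node_id -> (group_id, pathways)."""
    records = []
    for nid, spec in enzymes.items():
        group, pathways = (spec if isinstance(spec, tuple) else (spec, ()))
        records.append(
            NodeRecord(
                node_id=nid,
                organism_id=org,
                node_kind="enzyme",
                group_id=group,
                pathway_ids=frozenset(pathways),
            )
        )
    for nid, compound in dict(metabolites).items():
        records.append(
            NodeRecord(
                node_id=nid,
                organism_id=org,
                node_kind="metabolite",
                compound_id=compound,
            )
        )
    return MetabolicNetwork(org, records, edges, require_enzyme=False)


def cluster_world(member_groups):
    """Members {(org, node): group_id_or_None} -> (EnzymeCluster, networks)."""
    orgs = {}
    for (org, node), group in member_groups.items():
        orgs.setdefault(org, {})[node] = group
    networks = {org: make_enzyme_net(org, spec) for org, spec in orgs.items()}
    cluster = EnzymeCluster(1, frozenset(member_groups))
    return cluster, networks


def clusters_from_org_sets(org_sets):
    """Each entry is an iterable of organism ids; one synthetic enzyme each."""
    out = []
    for i, orgs in enumerate(org_sets):
        out.append(
            EnzymeCluster(i + 1, frozenset((org, f"e{i}") for org in orgs))
        )
    return out


@pytest.fixture
def two_path_networks():
    """Two isomorphic 4-node enzyme paths used by the mapping tests."""
    a = make_enzyme_net(
        "X",
        {f"a{i}": f"K{i}" for i in range(4)},
        edges=[("a0", "a1"), ("a1", "a2"), ("a2", "a3")],
    )
    b = make_enzyme_net(
        "Y",
        {f"b{i}": f"K{i}" for i in range(4)},
        edges=[("b0", "b1"), ("b1", "b2"), ("b2", "b3")],
    )
    return a, b


def random_enzyme_pair(rng, n_max=5):
    """Two random all-enzyme networks for oracle comparisons."""
    nets = []
    for org in ("X", "Y"):
        n = int(rng.integers(2, n_max + 1))
        ids = {f"{org.lower()}{i}": f"K{i}" for i in range(n)}
        pairs = list(itertools.combinations(sorted(ids), 2))
        edges = [p for p in pairs if rng.random() < 0.5]
        nets.append(make_enzyme_net(org, ids, edges=edges))
    return nets


def pairwise_sets(groups):
    out = set()
    for g in groups:
        for a, b in itertools.combinations(sorted(g), 2):
            out.add(frozenset((a, b)))
    return out
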