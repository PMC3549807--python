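import itertools

import numpy as np
import pytest

from netphylo import (
    AlignParams,
    NodePairScores,
    ValidationError,
    greedy_one_to_one,
    pairwise_scores,
)

from conftest import make_enzyme_net, random_enzyme_pair


def dense_fixed_point(net_a, net_b, prior, alpha):
    """Independent oracle: solve (I - alpha*M) r = (1-alpha) e directly.

    M is the neighborhood-spread operator over admissible (same-kind) node
    pairs, M[(i,j),(u,v)] = [u ~ i][v ~ j] / (deg(u) deg(v)); e is the prior
    normalized to total mass 1 over admissible pairs.  The returned vector is
    renormalized to mass 1 to match the library's output convention.
    """
    ids_a, ids_b = sorted(net_a.nodes), sorted(net_b.nodes)
    adm = [
        (i, j)
        for i in ids_a
        for j in ids_b
        if net_a.nodes[i].node_kind == net_b.nodes[j].node_kind
    ]
    index = {p: k for k, p in enumerate(adm)}
    nbr_a, nbr_b = net_a.neighbors(), net_b.neighbors()
    e = np.zeros(len(adm))
    for k, (i, j) in enumerate(adm):
        ra, rb = net_a.nodes[i], net_b.nodes[j]
        if ra.node_kind == "metabolite":
            if ra.compound_id is not None and ra.compound_id == rb.compound_id:
                e[k] = 1.0
        else:
            e[k] = prior.get(net_a.organism_id, i, net_b.organism_id, j)
    if e.sum() == 0:
        e = np.ones(len(adm))
    e = e / e.sum()
    m = np.zeros((len(adm), len(adm)))
    for k, (i, j) in enumerate(adm):
        for u in nbr_a[i]:
            for v in nbr_b[j]:
                kk = index.get((u, v))
                if kk is not None:
                    m[k, kk] = 1.0 / (len(nbr_a[u]) * len(nbr_b[v]))
    if alpha == 1.0:
        raise ValueError("oracle covers alpha < 1 only")
    r = np.linalg.solve(np.eye(len(adm)) - alpha * m, (1 - alpha) * e)
    r = r / r.sum()
    return {pair: val for pair, val in zip(adm, r)}


def as_vector(scores, net_a, net_b, pairs):
    return np.array(
        [
            scores.get(net_a.organism_id, i, net_b.organism_id, j)
            for i, j in pairs
        ]
    )


class TestPairwiseScores:
    def test_alpha_zero_returns_normalized_prior(self):
        a = make_enzyme_net("X", {"a1": "K1", "a2": "K2"}, edges=[("a1", "a2")])
        b = make_enzyme_net("Y", {"b1": "K1", "b2": "K2"})
        prior = NodePairScores()
        prior.set("X", "a1", "Y", "b1", 3.0)
        prior.set("X", "a2", "Y", "b2", 1.0)
        r = pairwise_scores(a, b, prior, AlignParams(alpha=0.0))
        assert r.get("X", "a1", "Y", "b1") == pytest.approx(0.75)
        assert r.get("X", "a2", "Y", "b2") == pytest.approx(0.25)

    def test_alpha_zero_topology_independent(self):
        prior = NodePairScores()
        prior.set("X", "a1", "Y", "b2", 2.0)
        prior.set("X", "a2", "Y", "b1", 1.0)
        nets = []
        for edges in ([("a1", "a2")], []):
            a = make_enzyme_net("X", {"a1": "K1", "a2": "K2"}, edges=edges)
            b = make_enzyme_net("Y", {"b1": "K1", "b2": "K2"})
            nets.append(pairwise_scores(a, b, prior, AlignParams(alpha=0.0)))
        assert nets[0] == nets[1]

    def test_pure_topology_symmetric_edge_is_uniform(self):
        a = make_enzyme_net("X", {"a1": None, "a2": None}, edges=[("a1", "a2")])
        b = make_enzyme_net("Y", {"b1": None, "b2": None}, edges=[("b1", "b2")])
        r = pairwise_scores(a, b, NodePairScores(), AlignParams(alpha=1.0))
        for i in ("a1", "a2"):
            for j in ("b1", "b2"):
                assert r.get("X", i, "Y", j) == pytest.approx(0.25)

    def test_all_zero_prior_falls_back_to_uniform(self, caplog):
        a = make_enzyme_net("X", {"a1": None, "a2": None})
        b = make_enzyme_net("Y", {"b1": None})
        with caplog.at_level("WARNING"):
            r = pairwise_scores(a, b, NodePairScores(), AlignParams(alpha=0.0))
        assert "uniform" in caplog.text
        assert r.get("X", "a1", "Y", "b1") == pytest.approx(0.5)

    def test_prior_with_unknown_node_rejected(self):
        a = make_enzyme_net("X", {"a1": None})
        b = make_enzyme_net("Y", {"b1": None})
        prior = NodePairScores()
        prior.set("X", "ghost", "Y", "b1", 1.0)
        with pytest.raises(ValidationError, match="ghost"):
            pairwise_scores(a, b, prior)

    def test_same_organism_rejected(self):
        a = make_enzyme_net("X", {"a1": None})
        with pytest.raises(ValidationError):
            pairwise_scores(a, a, NodePairScores())

    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.6, 0.9])
    def test_matches_dense_linear_solve(self, alpha):
        """Power iteration agrees with the closed-form fixed point to 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b = random_enzyme_pair(rng)
            prior = NodePairScores()
            for i in sorted(a.nodes):
                for j in sorted(b.nodes):
                    prior.set("X", i, "Y", j, float(rng.random()))
            got = pairwise_scores(a, b, prior, AlignParams(alpha=alpha))
            want = dense_fixed_point(a, b, prior, alpha)
            pairs = sorted(want)
            gv = as_vector(got, a, b, pairs)
            wv = np.array([want[p] for p in pairs])
            assert np.abs(gv - wv).sum() < 1e-8

    def test_returned_mass_sums_to_one(self):
        rng = np.random.default_rng(11)
        a, b = random_enzyme_pair(rng)
        r = pairwise_scores(a, b, NodePairScores(), AlignParams(alpha=0.6))
        total = sum(s for *_, s in r.canonical_items())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_mixed_kind_pairs_excluded(self):
        a = make_enzyme_net(
            "X", {"a1": "K1"}, metabolites={"m1": "C1"}, edges=[("a1", "m1")]
        )
        b = make_enzyme_net(
            "Y", {"b1": "K1"}, metabolites={"n1": "C1"}, edges=[("b1", "n1")]
        )
        r = pairwise_scores(a, b, NodePairScores(), AlignParams(alpha=0.6))
        assert r.get("X", "a1", "Y", "n1") == 0.0
        assert r.get("X", "m1", "Y", "b1") == 0.0
        assert r.get("X", "m1", "Y", "n1") > 0.0  # matching compounds conduct


class TestGreedyOneToOne:
    def test_greedy_order(self):
        r = NodePairScores()
        r.set("X", "a", "Y", "x", 0.9)
        r.set("X", "a", "Y", "y", 0.8)
        r.set("X", "b", "Y", "y", 0.7)
        assert greedy_one_to_one(r) == {"a": "x", "b": "y"}

    def test_tie_breaks_lexicographically(self):
        r = NodePairScores()
        r.set("X", "a", "Y", "x", 0.5)
        r.set("X", "a", "Y", "y", 0.5)
        assert greedy_one_to_one(r) == {"a": "x"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            greedy_one_to_one(NodePairScores())

    def test_recovers_planted_isomorphism(self, two_path_networks):
        """Identity-favoring prior on two isomorphic paths: greedy matches
        the brute-force best bijection, which is the planted one."""
        a, b = two_path_networks
        prior = NodePairScores()
        for i in range(4):
            for j in range(4):
                prior.set("X", f"a{i}", "Y", f"b{j}", 1.0 if i == j else 0.1)
        r = pairwise_scores(a, b, prior, AlignParams(alpha=0.6))
        mapping = greedy_one_to_one(r)

        nodes_a = [f"a{i}" for i in range(4)]
        nodes_b = [f"b{i}" for i in range(4)]
        best, best_total = None, -1.0
        for perm in itertools.permutations(nodes_b):
            total = sum(
                r.get("X", na, "Y", nb) for na, nb in zip(nodes_a, perm)
            )
            if total > best_total:
                best, best_total = dict(zip(nodes_a, perm)), total
        assert mapping == best
        assert mapping == {f"a{i}": f"b{i}" for i in range(4)}
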