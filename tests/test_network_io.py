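import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netphylo import (
    MetabolicNetwork,
    NodePairScores,
    NodeRecord,
    ValidationError,
    read_clusters,
    read_network,
    read_scores,
    write_clusters,
    write_network,
    write_scores,
)

NODES = """node_id\tkind\tgroup_id\tpathway_ids\tcompound_id
e1\tenzyme\tK00001\tko00010;ko00020\t
e2\tenzyme\tK00002\t\t
m1\tmetabolite\t\t\tC00001
"""


def _write(tmp_path, nodes=NODES, edges="e1\tm1\ne2\tm1\n"):
    np_, ep = tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
    np_.write_text(nodes)
    ep.write_text(edges)
    return np_, ep


class TestReadNetwork:
    def test_reads_nodes_and_edges(self, tmp_path):
        net = read_network(*_write(tmp_path), "eco")
        assert len(net.nodes) == 3
        assert len(net.edges) == 2
        assert net.nodes["e1"].pathway_ids == {"ko00010", "ko00020"}
        assert net.nodes["m1"].compound_id == "C00001"
        assert net.nodes["e2"].group_id == "K00002"

    def test_duplicate_edges_collapse(self, tmp_path):
        net = read_network(
            *_write(tmp_path, edges="e1\te2\ne2\te1\ne1\te2\n"), "eco"
        )
        assert net.edges == {("e1", "e2")}

    def test_unknown_edge_endpoint_named_in_error(self, tmp_path):
        paths = _write(tmp_path, edges="e1\tmissing_node\n")
        with pytest.raises(ValidationError, match="missing_node"):
            read_network(*paths, "eco")

    def test_duplicate_node_id_rejected(self, tmp_path):
        bad = NODES + "e1\tenzyme\tK9\t\t\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_network(*_write(tmp_path, nodes=bad), "eco")

    def test_comments_and_blanks_skipped(self, tmp_path):
        nodes = "# comment\n" + NODES + "\n# trailing\n"
        net = read_network(*_write(tmp_path, nodes=nodes), "eco")
        assert len(net.nodes) == 3

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            read_network(tmp_path / "nope.tsv", tmp_path / "nope2.tsv", "eco")


class TestNodeRecordInvariants:
    def test_metabolite_rejects_group_id(self):
        with pytest.raises(ValidationError):
            NodeRecord("m1", "eco", "metabolite", group_id="K1")

    def test_enzyme_rejects_compound_id(self):
        with pytest.raises(ValidationError):
            NodeRecord("e1", "eco", "enzyme", compound_id="C1")

    def test_whitespace_node_id_rejected(self):
        with pytest.raises(ValidationError):
            NodeRecord("e 1", "eco", "enzyme")

    def test_self_loop_rejected(self):
        rec = NodeRecord("e1", "eco", "enzyme")
        with pytest.raises(ValidationError):
            MetabolicNetwork("eco", [rec], [("e1", "e1")])


ids = st.text(string.ascii_lowercase + string.digits, min_size=1, max_size=6)


@st.composite
def networks(draw):
    n_e = draw(st.integers(1, 5))
    n_m = draw(st.integers(0, 3))
    records = [
        NodeRecord(
            f"e{i}",
            "org",
            "enzyme",
            group_id=draw(st.one_of(st.none(), ids)),
            pathway_ids=frozenset(draw(st.sets(ids, max_size=3))),
        )
        for i in range(n_e)
    ] + [
        NodeRecord(
            f"m{i}", "org", "metabolite",
            compound_id=draw(st.one_of(st.none(), ids)),
        )
        for i in range(n_m)
    ]
    node_ids = [r.node_id for r in records]
    pairs = [
        (a, b) for i, a in enumerate(node_ids) for b in node_ids[i + 1:]
    ]
    edges = draw(st.sets(st.sampled_from(pairs), max_size=6)) if pairs else set()
    return MetabolicNetwork("org", records, edges)


@given(networks())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_network_round_trip_identity(tmp_path_factory, net):
    tmp = tmp_path_factory.mktemp("rt")
    write_network(net, tmp / "n.tsv", tmp / "e.tsv")
    back = read_network(tmp / "n.tsv", tmp / "e.tsv", "org")
    assert back == net


def test_write_network_canonical_bytes(tmp_path):
    rec = [NodeRecord(f"e{i}", "o", "enzyme") for i in range(3)]
    n1 = MetabolicNetwork("o", rec, [("e0", "e1"), ("e1", "e2")])
    n2 = MetabolicNetwork("o", rec, [("e1", "e2"), ("e0", "e1")])
    write_network(n1, tmp_path / "a_n.tsv", tmp_path / "a_e.tsv")
    write_network(n2, tmp_path / "b_n.tsv", tmp_path / "b_e.tsv")
    assert (tmp_path / "a_n.tsv").read_bytes() == (tmp_path / "b_n.tsv").read_bytes()
    assert (tmp_path / "a_e.tsv").read_bytes() == (tmp_path / "b_e.tsv").read_bytes()


class TestScores:
    def test_symmetric_closure(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("X\te1\tY\tf1\t0.5\n")
        s = read_scores(p)
        assert s.get("X", "e1", "Y", "f1") == 0.5
        assert s.get("Y", "f1", "X", "e1") == 0.5

    def test_conflicting_duplicate_scores_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("X\te1\tY\tf1\t0.5\nY\tf1\tX\te1\t0.7\n")
        with pytest.raises(ValidationError, match=":2"):
            read_scores(p)

    def test_empty_file_empty_table(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("")
        assert len(read_scores(p)) == 0

    def test_negative_score_rejected_with_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("X\te1\tY\tf1\t0.5\nX\te2\tY\tf1\t-1\n")
        with pytest.raises(ValidationError, match=":2"):
            read_scores(p)

    def test_non_numeric_score_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("X\te1\tY\tf1\tabc\n")
        with pytest.raises(ValidationError, match="non-numeric"):
            read_scores(p)

    def test_same_organism_endpoints_rejected(self):
        s = NodePairScores()
        with pytest.raises(ValidationError):
            s.set("X", "e1", "X", "e2", 1.0)

    def test_round_trip(self, tmp_path):
        s = NodePairScores()
        s.set("X", "e1", "Y", "f1", 0.25)
        s.set("Y", "f2", "X", "e1", 0.125)
        write_scores(s, tmp_path / "s.tsv")
        assert read_scores(tmp_path / "s.tsv") == s


class TestClusters:
    def test_one_line_one_cluster(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("X|e1\tY|f1\n")
        assert read_clusters(p) == [{("X", "e1"), ("Y", "f1")}]

    def test_malformed_token_rejected_with_line(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("X|e1\tY|f1\nXe1\n")
        with pytest.raises(ValidationError, match=":2"):
            read_clusters(p)

    def test_round_trip_canonical(self, tmp_path):
        clusters = [
            {("Y", "f1"), ("X", "e1")},
            {("X", "e2")},
            {("Z", "g1"), ("X", "e3"), ("Y", "f9")},
        ]
        write_clusters(clusters, tmp_path / "a.tsv")
        back = read_clusters(tmp_path / "a.tsv")
        write_clusters(back, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert sorted(map(sorted, back)) == sorted(map(sorted, clusters))

    def test_entropy_column_written_and_ignored_on_read(self, tmp_path):
        write_clusters(
            [{("X", "e1"), ("Y", "f1")}], tmp_path / "c.tsv", entropies={0: 0.25}
        )
        text = (tmp_path / "c.tsv").read_text()
        assert text.strip().endswith("0.250000")
        assert read_clusters(tmp_path / "c.tsv") == [{("X", "e1"), ("Y", "f1")}]
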