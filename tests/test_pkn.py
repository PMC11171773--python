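import logging

import pytest

from tcsignal.pkn import (Edge, KnowledgeNetwork, Mechanism, Node, NodeKind,
                          ParseError, Sign, ValidationError, expand_virtual,
                          filter_by_if, mechanism_view, path_view_graph,
                          read_network, write_network)


TSV_HEADER = "source\ttarget\tsign\tmechanism\tif_score\treference\n"


def write_tsv(tmp_path, rows, name="net.tsv"):
    path = tmp_path / name
    path.write_text(TSV_HEADER + "".join(r + "\n" for r in rows))
    return str(path)


class TestReadNetwork:
    def test_three_line_tsv(self, tmp_path):
        path = write_tsv(tmp_path, [
            "A\tB\tactivation\ttranscriptional_regulation\t0.9\tref1",
            "B\tC\trepression\ttranscriptional_regulation\t0.95\tref2",
        ])
        net = read_network(path)
        assert len(net.nodes) == 3
        assert len(net.edges) == 2
        assert all(e.directed for e in net.edges)
        assert net.edges[1].sign is Sign.REPRESSION

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        net = read_network(str(path))
        assert net.nodes == {} and net.edges == []

    def test_unknown_sign_maps_to_unknown_with_warning(self, tmp_path, caplog):
        path = write_tsv(tmp_path, ["A\tB\tact.\tppi\t0.9\tr"])
        with caplog.at_level(logging.WARNING):
            net = read_network(path)
        assert net.edges[0].sign is Sign.UNKNOWN
        assert any("act." in rec.message for rec in caplog.records)

    def test_malformed_row_names_line(self, tmp_path):
        path = write_tsv(tmp_path, ["A\tB\tactivation\ttranscriptional_regulation\t0.9\tr",
                                    "A\tonly_two"])
        with pytest.raises(ParseError, match=":3"):
            read_network(path)

    def test_sif_dialect(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("A\tactivation\tB\tC\nB\trepression:ppi\tD\n")
        net = read_network(str(path), dialect="sif")
        assert len(net.edges) == 3
        assert net.edges[2].mechanism is Mechanism.PPI

    def test_roundtrip_tsv_bit_exact(self, tmp_path):
        path = write_tsv(tmp_path, [
            "A\tB\tactivation\ttranscriptional_regulation\t0.863512\tr1",
            "A\tB\tactivation\tppi\t0.55\tr2",  # duplicate pair, distinct provenance
            "B\tC\tunknown\tcorrelation\t0.7\tr3",
        ])
        net = read_network(path)
        out = str(tmp_path / "out.tsv")
        write_network(net, out)
        net2 = read_network(out)
        assert set(net2.nodes) == set(net.nodes)
        assert net2.edges == net.edges

    def test_graphml_roundtrip(self, tmp_path):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", Sign.ACTIVATION, Mechanism.TRANSCRIPTIONAL, 0.9, "r"))
        net.add_complex("CX", ("A", "B"))
        out = str(tmp_path / "net.graphml")
        write_network(net, out, dialect="graphml")
        net2 = read_network(out, dialect="graphml")
        assert net2.nodes["CX"].kind is NodeKind.COMPLEX
        assert net2.nodes["CX"].members == ("A", "B")
        assert net2.edges == net.edges


class TestFilterByIf:
    def test_threshold_086_flags_lower(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", if_score=0.9))
        net.add_edge(Edge("B", "C", if_score=0.85))
        out = filter_by_if(net, 0.86)
        assert [e.low_confidence for e in out.edges] == [False, True]
        assert len(out.edges) == 2  # marked, never removed

    def test_threshold_zero_flags_nothing(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", if_score=0.1))
        assert not any(e.low_confidence for e in filter_by_if(net, 0.0).edges)

    def test_boundary_strict_inequality(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", if_score=0.86))
        assert not filter_by_if(net, 0.86).edges[0].low_confidence

    def test_idempotent(self):
        net = KnowledgeNetwork()
        for score in (0.5, 0.86, 0.99):
            net.add_edge(Edge("A", "B", if_score=score))
        once = filter_by_if(net, 0.86)
        twice = filter_by_if(once, 0.86)
        assert once.edges == twice.edges


class TestExpandVirtual:
    def test_complex_gets_member_edges(self):
        net = KnowledgeNetwork()
        net.ensure_node("flhD")
        net.ensure_node("flhC")
        net.add_complex("FlhDC", ("flhD", "flhC"))
        out = expand_virtual(net)
        virtuals = [e for e in out.edges if e.mechanism is Mechanism.VIRTUAL]
        assert {(e.source, e.target) for e in virtuals} == {("flhD", "FlhDC"), ("flhC", "FlhDC")}
        assert all(e.sign is Sign.ACTIVATION and e.directed for e in virtuals)

    def test_no_complexes_identity(self, toy_regulatory_net):
        out = expand_virtual(toy_regulatory_net)
        assert out.edges == toy_regulatory_net.edges
        assert set(out.nodes) == set(toy_regulatory_net.nodes)

    def test_unknown_member_errors_with_name(self):
        net = KnowledgeNetwork()
        net.ensure_node("a")
        net.nodes["CX"] = Node("CX", NodeKind.COMPLEX, ("a", "ghost", "b"))
        with pytest.raises(ValidationError, match="ghost"):
            expand_virtual(net)

    def test_adds_exactly_sum_of_members_and_zero_nodes(self):
        net = KnowledgeNetwork()
        for n in "abcde":
            net.ensure_node(n)
        net.add_complex("C1", ("a", "b"))
        net.add_complex("C2", ("c", "d", "e"))
        out = expand_virtual(net)
        assert len(out.edges) - len(net.edges) == 5
        assert set(out.nodes) == set(net.nodes)


class TestMechanismView:
    def test_correlation_only(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", mechanism=Mechanism.TRANSCRIPTIONAL))
        net.add_edge(Edge("B", "C", mechanism=Mechanism.CORRELATION))
        out = mechanism_view(net, {Mechanism.CORRELATION})
        assert len(out.edges) == 1 and not out.edges[0].directed
        assert set(out.nodes) == {"B", "C"}

    def test_all_mechanisms_is_identity(self, toy_regulatory_net):
        out = mechanism_view(toy_regulatory_net, set(Mechanism))
        assert out.edges == toy_regulatory_net.edges
        assert set(out.nodes) == set(toy_regulatory_net.nodes)

    def test_vacuous_view_empty(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", mechanism=Mechanism.CORRELATION))
        out = mechanism_view(net, {Mechanism.TRANSCRIPTIONAL})
        assert out.edges == [] and out.nodes == {}


class TestPathView:
    def test_ppi_traversed_both_ways_correlation_excluded(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", mechanism=Mechanism.PPI))
        net.add_edge(Edge("B", "C", mechanism=Mechanism.CORRELATION))
        g = path_view_graph(net)
        assert g.has_edge("A", "B") and g.has_edge("B", "A")
        assert "C" not in g

    def test_low_confidence_excluded_by_default(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", if_score=0.5, low_confidence=True))
        assert path_view_graph(net).number_of_edges() == 0
        assert path_view_graph(net, include_low_confidence=True).has_edge("A", "B")

    def test_parallel_edges_collapse_to_max_if(self):
        net = KnowledgeNetwork()
        net.add_edge(Edge("A", "B", Sign.ACTIVATION, if_score=0.7))
        net.add_edge(Edge("A", "B", Sign.REPRESSION, if_score=0.95))
        g = path_view_graph(net)
        assert g["A"]["B"]["if_score"] == 0.95
        assert g["A"]["B"]["sign"] == "repression"
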