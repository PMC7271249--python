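"""Network construction, protein/network/screen queries and export."""

import numpy as np
import pytest

import ppiref
from ppiref.errors import NotFoundError, PpirefError
from ppiref.mitab import EvidenceBundle
from ppiref.network import (
    PSEUDO_SCORE,
    QueryOptions,
    build_network,
    export,
    filter_confidence,
    network_query,
    parse_screen_file,
    protein_query,
    screen_annotate,
)
from ppiref.scoring import ScoredInteraction


def _scored(a, b, score, studies=("pubmed:1",), techniques=("MI:0018",)):
    bundle = EvidenceBundle(
        pair=(a, b),
        interaction_types={"MI:0915"},
        studies=set(studies),
        techniques=set(techniques),
    )
    return ScoredInteraction(bundle.pair, score, 0.0, 0.0, 0.0, bundle)


def _net(edges):
    return build_network([_scored(a, b, s) for a, b, s in edges])


class TestBuild:
    def test_counts_from_direct_construction(self):
        net = _net([(1, 2, 0.5), (3, 4, 0.5), (5, 6, 0.5), (1, 3, 0.5), (2, 4, 0.5)])
        assert net.n_proteins == 6
        assert net.n_interactions == 5

    def test_mean_incident_score_hand_average(self):
        net = _net([(1, 2, 0.2), (2, 3, 0.4), (1, 3, 0.6)])
        assert net.graph.nodes[2]["mean_score"] == pytest.approx(0.3)

    def test_empty_input_gives_empty_network(self):
        net = build_network([])
        assert net.n_proteins == 0 and net.n_interactions == 0

    def test_self_loop_counts_once_in_degree(self):
        net = _net([(1, 1, 0.5), (1, 2, 0.6)])
        assert net.graph.nodes[1]["degree"] == 2  # itself + node 2
        assert net.n_proteins == 2

    def test_no_isolated_nodes_by_construction(self):
        net = _net([(1, 2, 0.5)])
        assert all(
            net.graph.degree(n) > 0 for n in net.graph.nodes
        )


class TestProteinQuery:
    def test_partner_scores_non_increasing(self):
        net = _net([(1, 2, 0.3), (1, 3, 0.9), (1, 4, 0.6), (1, 5, 0.6)])
        table = protein_query(net, "1")
        assert len(table) == 4
        scores = list(table["score"])
        assert scores == sorted(scores, reverse=True)

    def test_symbol_and_entrez_queries_agree(self, hippo):
        by_symbol = protein_query(hippo.net, "Lats2")
        by_entrez = protein_query(hippo.net, "103")
        assert by_symbol.equals(by_entrez)

    def test_hippo_partner_set_matches_adjacency(self, hippo):
        table = protein_query(hippo.net, "Lats2")
        assert set(table["partner_symbol"]) == {"Stk4", "Yap1", "Wwtr1"}

    def test_evidence_detail_columns_present(self, hippo):
        table = protein_query(hippo.net, "Stk4")
        assert set(table["interolog_species"]) == {"9606"}
        assert all("pubmed:" in p for p in table["publications"])

    def test_unresolvable_identifier_raises(self, hippo):
        with pytest.raises(NotFoundError):
            protein_query(hippo.net, "Nosuchgene")

    def test_mgi_and_uniprot_resolution(self, hippo):
        mgi = hippo.net.graph.nodes[103]["mgi"]
        uni = hippo.net.graph.nodes[103]["uniprot"]
        assert hippo.net.resolve(mgi) == 103
        assert hippo.net.resolve(uni) == 103


class TestNetworkQuery:
    def test_present_pair_reported_with_its_score(self):
        net = _net([(1, 2, 0.7), (2, 3, 0.4)])
        res = network_query(net, [(1, 2)], QueryOptions(layers=0))
        assert res.graph.edges[1, 2]["score"] == 0.7
        assert res.pseudo_pairs == []

    def test_absent_pair_gets_pseudo_score(self):
        net = _net([(1, 2, 0.7)])
        res = network_query(net, [("1", "99")])
        assert res.pseudo_pairs == [(1, "99")]
        table = res.edge_table()
        assert PSEUDO_SCORE in set(table["score"])

    def test_layers_zero_restricts_to_input_set(self):
        net = _net([(1, 2, 0.5), (2, 3, 0.5), (3, 4, 0.5)])
        res = network_query(net, ["1", "2", "3"], QueryOptions(layers=0))
        assert sorted(res.graph.edges) == [(1, 2), (2, 3)]

    def test_layers_zero_on_all_nodes_returns_full_edge_set(self, hippo):
        nodes = [str(n) for n in hippo.net.graph.nodes]
        res = network_query(hippo.net, nodes, QueryOptions(layers=0))
        assert set(map(frozenset, res.graph.edges)) == set(
            map(frozenset, hippo.net.graph.edges)
        )

    def test_min_connections_prunes_single_link_neighbors(self):
        # star: neighbors 10..13 touch one input each; 20 touches both inputs
        net = _net(
            [(1, 10, 0.5), (1, 11, 0.5), (2, 12, 0.5), (2, 13, 0.5),
             (1, 20, 0.5), (2, 20, 0.5), (1, 2, 0.5)]
        )
        res = network_query(net, ["1", "2"], QueryOptions(min_connections=2))
        expected_nodes = {1, 2, 20}  # brute-force: only 20 has >= 2 input links
        assert set(res.graph.nodes) == expected_nodes

    def test_min_connections_monotone(self):
        rng = np.random.default_rng(3)
        edges = {(int(a), int(b)) for a, b in rng.integers(1, 15, size=(40, 2)) if a != b}
        net = _net([(a, b, 0.5) for a, b in edges])
        inputs = [str(n) for n in list(net.graph.nodes)[:4]]
        prev = None
        for mc in (1, 2, 3):
            res = network_query(net, inputs, QueryOptions(min_connections=mc))
            n_edges = res.graph.number_of_edges()
            if prev is not None:
                assert n_edges <= prev
            prev = n_edges

    def test_confidence_and_tissue_filters_commute(self, hippo):
        inputs = ["Stk4", "Lats2", "Tead4"]
        both = network_query(
            hippo.net,
            inputs,
            QueryOptions(threshold=0.6, tissue_filter="trophoblast"),
            calls=hippo.calls,
        )
        conf_then_tissue = filter_confidence(
            network_query(
                hippo.net,
                inputs,
                QueryOptions(tissue_filter="trophoblast"),
                calls=hippo.calls,
            ),
            0.6,
        )
        assert sorted(map(tuple, both.graph.edges)) == sorted(
            map(tuple, conf_then_tissue.graph.edges)
        )

    def test_named_threshold_levels(self):
        net = _net([(1, 2, 0.55), (1, 3, 0.65), (1, 4, 0.3)])
        res = network_query(net, ["1"], QueryOptions(threshold="high"))
        assert sorted(res.graph.edges) == [(1, 3)]
        res = network_query(net, ["1"], QueryOptions(threshold="medium"))
        assert sorted(res.graph.edges) == [(1, 2), (1, 3)]

    def test_type_filter_conjunction(self):
        net = _net([(1, 2, 0.5), (1, 3, 0.5)])
        res = network_query(
            net, ["1"], QueryOptions(type_filter={"MI:0407"})
        )
        assert res.graph.number_of_edges() == 0

    def test_empty_input_rejected(self, hippo):
        with pytest.raises(PpirefError):
            network_query(hippo.net, [])


class TestFilterConfidence:
    def test_zero_threshold_is_identity(self):
        net = _net([(1, 2, 0.5), (2, 3, 0.1)])
        out = filter_confidence(net.graph, 0.0)
        assert sorted(out.edges) == sorted(net.graph.edges)

    def test_above_maximum_removes_everything(self):
        net = _net([(1, 2, 0.5), (2, 3, 0.9)])
        assert filter_confidence(net.graph, 0.91).number_of_edges() == 0

    def test_inclusive_at_the_cutoff(self):
        net = _net([(1, 2, 0.6)])
        assert filter_confidence(net.graph, 0.6).number_of_edges() == 1

    def test_median_cutoff_matches_counting_oracle(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(0, 1, size=20)
        net = _net([(i, 100 + i, float(s)) for i, s in enumerate(scores)])
        median = float(np.median(scores))
        expected = int(np.sum(scores >= median))
        assert filter_confidence(net.graph, median).number_of_edges() == expected

    def test_pseudo_rows_exempt(self):
        net = _net([(1, 2, 0.7)])
        res = network_query(net, [("1", "99")])
        out = filter_confidence(res, 0.99)
        assert out.pseudo_pairs == res.pseudo_pairs

    def test_threshold_monotone(self):
        net = _net([(i, i + 100, s) for i, s in enumerate([0.1, 0.4, 0.6, 0.9])])
        prev = None
        for thr in (0.0, 0.3, 0.5, 0.8, 1.0):
            n = filter_confidence(net.graph, thr).number_of_edges()
            if prev is not None:
                assert n <= prev
            prev = n


class TestScreenAnnotate:
    def test_known_and_unknown_pairs(self):
        net = _net([(1, 2, 0.7), (3, 4, 0.2), (5, 6, 0.9)])
        table = screen_annotate(
            [("1", "2"), ("3", "4"), ("5", "6"), ("1", "9"), ("7", "8")], net
        )
        assert list(table["score"]) == [0.7, 0.2, 0.9, -1.0, -1.0]

    def test_empty_candidate_list(self):
        table = screen_annotate([], _net([(1, 2, 0.5)]))
        assert len(table) == 0
        assert list(table.columns) == ["a", "b", "score"]

    def test_all_known_pairs_have_no_sentinel(self):
        edges = [(i, i + 50, 0.5 + i / 100) for i in range(10)]
        net = _net(edges)
        table = screen_annotate([(str(a), str(b)) for a, b, _ in edges], net)
        assert (table["score"] != PSEUDO_SCORE).all()

    def test_agrees_with_protein_query_scores(self, hippo):
        partners = protein_query(hippo.net, "Lats2")
        pairs = [("Lats2", str(p)) for p in partners["partner_entrez"]]
        screened = screen_annotate(pairs, hippo.net)
        assert list(screened["score"]) == list(partners["score"])

    def test_row_order_preserved(self):
        net = _net([(1, 2, 0.5)])
        table = screen_annotate([("9", "9"), ("1", "2")], net)
        assert list(table["a"]) == ["9", "1"]


class TestScreenFileParsing:
    @pytest.mark.parametrize("sep", ["\t", ",", ";"])
    def test_all_three_separators(self, tmp_path, sep):
        path = tmp_path / "pairs.txt"
        path.write_text(f"a{sep}b\nc{sep}d\n")
        assert parse_screen_file(path) == [("a", "b"), ("c", "d")]

    def test_unparseable_line_names_line(self, tmp_path):
        path = tmp_path / "pairs.txt"
        path.write_text("a\tb\njustone\n")
        with pytest.raises(Exception, match="line 2"):
            parse_screen_file(path)


class TestExport:
    def test_mitab_roundtrip_preserves_pair_set(self, hippo, tmp_path):
        res = network_query(hippo.net, ["Stk4", "Lats2", "Tead4"])
        out = export(res, "mitab", tmp_path / "sub.mitab")
        rows = ppiref.parse_mitab(out)
        # pair identity via entrez accessions embedded in the id column
        pairs = {
            tuple(sorted((int(r.interactor_a_raw.split(":")[-1]),
                          int(r.interactor_b_raw.split(":")[-1]))))
            for r in rows
        }
        assert pairs == {tuple(sorted(e)) for e in res.graph.edges}

    def test_tsv_line_count(self, hippo, tmp_path):
        res = network_query(hippo.net, ["Lats2"], QueryOptions(layers=1))
        out = export(res, "tsv", tmp_path / "sub.tsv")
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 1 + res.graph.number_of_edges()

    def test_json_graph_node_count_matches_order(self, hippo, tmp_path):
        import json

        for inputs in (["Stk4"], ["Lats2", "Tead4"], ["Yap1"]):
            res = network_query(hippo.net, inputs)
            out = export(res, "json-graph", tmp_path / "g.json")
            data = json.loads(out.read_text())
            assert len(data["nodes"]) == res.graph.number_of_nodes()
            assert len(data["edges"]) == res.graph.number_of_edges()

    def test_unknown_format_rejected(self, hippo, tmp_path):
        res = network_query(hippo.net, ["Stk4"])
        with pytest.raises(PpirefError):
            export(res, "xml", tmp_path / "x")
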