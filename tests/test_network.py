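"""Network construction rules, community detection, summaries."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosrewire import diffreg, network, simulate
from phosrewire.datamodel import ValidationError
from phosrewire.simulate import GroundTruth, SimConfig


def _interactions(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


def _call(gene, status, pid=None, pos=1):
    return diffreg.RegulationCall(
        unit_key=(pid or ("P_" + gene), pos, 1), gene=gene, z=(0.0,) * 4,
        n_up=0, n_down=0, n_quantified=4, status=status, mean_log2fc=1.0
        if status == "up" else -1.0 if status == "down" else 0.0)


class TestFilterHighConfidence:
    def test_threshold_inclusive(self):
        df = _interactions([("A", "B", 0.9), ("A", "C", 0.7),
                            ("B", "C", 0.69)])
        kept = network.filter_high_confidence(df, 0.7)
        assert len(kept) == 2

    def test_zero_threshold_is_identity(self):
        df = _interactions([("A", "B", 0.1)])
        assert network.filter_high_confidence(df, 0.0).equals(df)

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValidationError):
            network.filter_high_confidence(_interactions([]), 1.01)


class TestKinomeNetwork:
    def _ksr(self, rows):
        return pd.DataFrame(rows, columns=["kinase", "substrate_protein",
                                           "substrate_position", "source"])

    def test_kinase_with_up_substrate(self):
        calls = [_call("GS", "up", pid="P1", pos=10)]
        g = network.build_kinome_network(
            calls, self._ksr([("K1", "P1", 10, "curated")]))
        assert set(g) == {"K1", "GS"}
        assert g.edges["K1", "GS"]["direction"] == "up"
        assert g.edges["K1", "GS"]["provenance"] == "ksr"
        assert g.nodes["K1"]["is_kinase"]

    def test_kinase_without_regulated_substrate_excluded(self):
        calls = [_call("GS", "unchanged", pid="P1", pos=10)]
        g = network.build_kinome_network(
            calls, self._ksr([("K1", "P1", 10, "curated")]))
        assert g.number_of_nodes() == 0

    def test_ppi_edge_between_included_substrates_retained(self):
        calls = [_call("GA", "up", pid="P1", pos=10),
                 _call("GB", "down", pid="P2", pos=5)]
        ksr = self._ksr([("K1", "P1", 10, "curated"),
                         ("K1", "P2", 5, "curated")])
        ppi = _interactions([("GA", "GB", 0.9), ("GA", "ZZ", 0.9)])
        g = network.build_kinome_network(calls, ksr, interactions=ppi)
        assert g.edges["GA", "GB"]["provenance"] == "ppi"
        assert "ZZ" not in g


class TestIntegratedNetwork:
    def test_both_endpoint_rule(self):
        calls = [_call("A", "up"), _call("B", "down"), _call("C", "up")]
        edges = _interactions([("A", "B", 0.9), ("A", "D", 0.9),
                               ("C", "B", 0.8)])
        g = network.build_integrated_network(calls, [], edges)
        assert set(g) == {"A", "B", "C"}
        assert set(map(frozenset, g.edges)) == \
            {frozenset({"A", "B"}), frozenset({"C", "B"})}

    def test_edge_filter_soundness_exhaustive(self, small_study):
        calls = diffreg.run_diffreg(small_study.phospho, small_study.design)
        tfs = sorted(small_study.truth.active_tfs)
        g = network.build_integrated_network(
            calls, tfs, small_study.annotations.interactions)
        phos_up, phos_down = diffreg.gene_direction_sets(calls)
        eligible = phos_up | phos_down | set(tfs)
        for u, v in g.edges:
            assert u in eligible and v in eligible

    def test_bridging_flag_relaxes_to_one_endpoint(self):
        calls = [_call("A", "up")]
        edges = _interactions([("A", "D", 0.9), ("D", "E", 0.9)])
        g = network.build_integrated_network(calls, [], edges,
                                             include_bridging=True)
        assert set(g) == {"A", "D"}

    def test_empty_overlap_warns(self):
        calls = [_call("A", "up")]
        edges = _interactions([("X", "Y", 0.9)])
        with pytest.warns(UserWarning):
            g = network.build_integrated_network(calls, [], edges)
        assert g.number_of_nodes() == 0

    def test_node_carrying_both_flags(self):
        calls = [_call("A", "up"), _call("B", "down")]
        edges = _interactions([("A", "B", 0.9)])
        g = network.build_integrated_network(
            calls, ["A"], edges, tf_direction={"A": "down"})
        assert g.nodes["A"]["regulated_phospho"] == "up"
        assert g.nodes["A"]["tf_status"] == "down"


class TestCommunities:
    def test_barbell_matches_exhaustive_modularity_oracle(self):
        """Two 3-cliques joined by one bridge: best partition over all 203
        set partitions of the 6 nodes is the two cliques."""
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"),
                          ("d", "e"), ("d", "f"), ("e", "f"),
                          ("c", "d")])
        nodes = sorted(g)

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        best = max(partitions(nodes),
                   key=lambda p: nx.community.modularity(
                       g, [set(b) for b in p]))
        best_sets = {frozenset(b) for b in best}
        comm = network.detect_communities(g)
        got = {}
        for node, cid in comm.partition.items():
            got.setdefault(cid, set()).add(node)
        assert {frozenset(s) for s in got.values()} == best_sets
        assert best_sets == {frozenset("abc"), frozenset("def")}
        assert comm.modularity == pytest.approx(
            nx.community.modularity(g, [set("abc"), set("def")]))

    def test_single_clique_is_one_community(self):
        g = nx.complete_graph(5)
        comm = network.detect_communities(g)
        assert len(set(comm.partition.values())) == 1

    def test_planted_sbm_recovered(self):
        from sklearn.metrics import rand_score
        cfg = SimConfig(seed=3, community_sizes=(20, 20), p_within=0.6,
                        p_between=0.02)
        truth = GroundTruth()
        nodes = [f"N{i:02d}" for i in range(40)]
        edges = simulate.simulate_interactome(cfg, truth, nodes)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges[["node_a", "node_b"]].itertuples(index=False))
        comm = network.detect_communities(g)
        labels_true = [truth.community_assignment[n] for n in nodes]
        labels_pred = [comm.partition[n] for n in nodes]
        assert rand_score(labels_true, labels_pred) >= 0.95

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            network.detect_communities(nx.Graph())

    def test_partition_beats_trivial_one_community(self, small_study):
        g = nx.Graph()
        inter = small_study.annotations.interactions
        g.add_edges_from(inter[["node_a", "node_b"]].itertuples(index=False))
        comm = network.detect_communities(g)
        groups: dict[int, set] = {}
        for n, c in comm.partition.items():
            groups.setdefault(c, set()).add(n)
        trivial = nx.community.modularity(g, [set(g)])
        assert comm.modularity >= trivial

    def test_determinism(self, small_study):
        g = nx.Graph()
        inter = small_study.annotations.interactions
        g.add_edges_from(inter[["node_a", "node_b"]].itertuples(index=False))
        assert (network.detect_communities(g).partition
                == network.detect_communities(g).partition)


class TestStats:
    def test_counts(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B", "C"])
        g.add_edges_from([("A", "B"), ("B", "C")])
        s = network.network_stats(g)
        assert (s["n_nodes"], s["n_edges"]) == (3, 2)

    def test_empty(self):
        s = network.network_stats(nx.Graph())
        assert (s["n_nodes"], s["n_edges"]) == (0, 0)

    def test_flag_tallies(self):
        g = nx.Graph()
        g.add_node("A", regulated_phospho="up", is_kinase=False,
                   tf_status="none")
        g.add_node("B", regulated_phospho="up", is_kinase=True,
                   tf_status="none")
        g.add_node("C", regulated_phospho="none", is_kinase=False,
                   tf_status="down")
        s = network.network_stats(g)
        assert s["n_phospho_up"] == 2
        assert s["n_tfs"] == 1
        assert s["n_kinases"] == 1
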