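"""Typed network construction: confidence filtering, the four builders, accounting."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netpharm.netbuild import (
    TypedNetwork,
    build_bipartite_network,
    build_disease_network,
    expand_network,
    filter_ppi,
    increment_report,
    merge_networks,
)


def edges_df(rows):
    return pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])


class TestFilterPpi:
    def test_strict_threshold(self):
        df = edges_df([("A", "B", 0.39), ("A", "C", 0.40), ("A", "D", 0.41)])
        out = filter_ppi(df)
        assert list(out.itertuples(index=False, name=None)) == [("A", "D", 0.41)]

    def test_duplicate_pairs_keep_max_confidence(self):
        df = edges_df([("A", "B", 0.5), ("B", "A", 0.7)])
        out = filter_ppi(df)
        assert len(out) == 1
        assert out.loc[0, "confidence"] == 0.7

    def test_self_loops_dropped(self):
        out = filter_ppi(edges_df([("A", "A", 0.9), ("A", "B", 0.9)]))
        assert len(out) == 1

    def test_malformed_confidence_rejected(self):
        with pytest.raises(ValueError, match="malformed confidence"):
            filter_ppi(edges_df([("A", "B", 1.7)]))
        with pytest.raises(ValueError, match="malformed confidence"):
            filter_ppi(edges_df([("A", "B", "high")]))


class TestDiseaseNetwork:
    def test_isolated_genes_dropped(self):
        net = build_disease_network(["A", "B", "C"], edges_df([("A", "B", 0.9)]))
        assert set(net.graph.nodes) == {"A", "B"} and net.n_edges == 1
        assert net.role_counts() == {"disease_target": 2}

    def test_induced_semantics_only_within_set_edges(self):
        net = build_disease_network(["A", "B"], edges_df([("A", "X", 0.9)]))
        assert net.n_nodes == 0

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_disease_network([], edges_df([("A", "B", 0.9)]))


class TestBipartiteNetwork:
    def test_complete_bipartite_counts(self):
        assoc = pd.DataFrame(
            [(c, g) for c in ("c1", "c2") for g in ("g1", "g2", "g3")],
            columns=["compound_id", "gene_id"],
        )
        net = build_bipartite_network(assoc)
        assert net.n_nodes == 5 and net.n_edges == 6
        assert net.role_counts() == {"compound": 2, "compound_target": 3}

    def test_empty_table_gives_empty_network(self):
        net = build_bipartite_network(pd.DataFrame(columns=["compound_id", "gene_id"]))
        assert net.n_nodes == 0

    def test_duplicate_rows_counted_once(self):
        assoc = pd.DataFrame([("c1", "g1"), ("c1", "g1")], columns=["compound_id", "gene_id"])
        assert build_bipartite_network(assoc).n_edges == 1

    def test_identifier_collision_rejected(self):
        assoc = pd.DataFrame([("x", "y"), ("z", "x")], columns=["compound_id", "gene_id"])
        with pytest.raises(ValueError, match="collision|both compound and gene"):
            build_bipartite_network(assoc)


def toy_nets():
    drug = build_bipartite_network(
        pd.DataFrame([("c1", "A"), ("c1", "B"), ("c2", "B")], columns=["compound_id", "gene_id"])
    )
    disease = build_disease_network(["B", "C", "D"], edges_df([("C", "D", 0.9), ("B", "C", 0.8)]))
    return drug, disease


class TestMerge:
    def test_disjoint_union_counts(self):
        drug = build_bipartite_network(
            pd.DataFrame([("c1", "A")], columns=["compound_id", "gene_id"])
        )
        disease = build_disease_network(["X", "Y"], edges_df([("X", "Y", 0.9)]))
        merged, report = merge_networks(drug, disease, edges_df([]))
        assert merged.n_nodes == drug.n_nodes + disease.n_nodes
        assert merged.n_edges == drug.n_edges + disease.n_edges
        assert report["vs_compound_target_network"] == {"nodes_added": 2, "edges_added": 1}
        assert report["vs_disease_network"] == {"nodes_added": 2, "edges_added": 1}

    def test_shared_target_role(self):
        drug, disease = toy_nets()
        merged, _ = merge_networks(drug, disease, edges_df([]))
        roles = dict(merged.graph.nodes(data="role"))
        assert roles["B"] == "shared_target"
        assert roles["A"] == "compound_target"
        assert roles["C"] == "disease_target"

    def test_ppi_edges_added_among_protein_nodes_only(self):
        drug, disease = toy_nets()
        ppi = edges_df([("A", "D", 0.9), ("A", "zzz", 0.9)])  # zzz not in either net
        merged, _ = merge_networks(drug, disease, ppi)
        assert merged.graph.has_edge("A", "D")
        assert "zzz" not in merged.graph

    def test_role_contradiction_rejected(self):
        drug = build_bipartite_network(
            pd.DataFrame([("c1", "A")], columns=["compound_id", "gene_id"])
        )
        disease = build_disease_network(["c1", "B"], edges_df([("c1", "B", 0.9)]))
        with pytest.raises(ValueError, match="both compound and protein"):
            merge_networks(drug, disease, edges_df([]))

    def test_union_identity_on_random_toys(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_c, n_g = rng.integers(1, 5), rng.integers(2, 8)
            compounds = [f"c{i}" for i in range(n_c)]
            genes = [f"g{i}" for i in range(n_g)]
            assoc = pd.DataFrame(
                [(c, g) for c in compounds for g in genes if rng.random() < 0.5],
                columns=["compound_id", "gene_id"],
            )
            if assoc.empty:
                continue
            dg = [f"g{i}" for i in range(n_g) if rng.random() < 0.6] + ["d0", "d1"]
            ppi_rows = [
                (a, b, 0.41 + 0.59 * rng.random())
                for a in dg
                for b in dg + genes
                if a < b and rng.random() < 0.4
            ]
            ppi = filter_ppi(edges_df(ppi_rows)) if ppi_rows else edges_df([])
            drug = build_bipartite_network(assoc)
            disease = build_disease_network(dg, ppi)
            merged, report = merge_networks(drug, disease, ppi)
            # exact set union of nodes, exact increment arithmetic
            assert set(merged.graph.nodes) == set(drug.graph.nodes) | set(disease.graph.nodes)
            assert report["vs_compound_target_network"]["nodes_added"] == merged.n_nodes - drug.n_nodes
            assert report["vs_disease_network"]["edges_added"] == merged.n_edges - disease.n_edges
            # role partition is exhaustive and exclusive
            assert all(r is not None for _, r in merged.graph.nodes(data="role"))


class TestExpand:
    def test_one_hop_rule(self):
        core = build_disease_network(["A", "B"], edges_df([("A", "B", 0.9)]))
        ppi = edges_df([("A", "B", 0.9), ("A", "X", 0.9), ("X", "Y", 0.9)])
        expanded, report = expand_network(core, ppi)
        assert set(expanded.graph.nodes) == {"A", "B", "X"}  # Y is two hops out
        assert expanded.graph.nodes["X"]["role"] == "other_protein"
        assert report["vs_core_network"] == {"nodes_added": 1, "edges_added": 1}

    def test_edges_between_added_neighbors_included(self):
        core = build_disease_network(["A", "B"], edges_df([("A", "B", 0.9)]))
        ppi = edges_df([("A", "X", 0.9), ("B", "Y", 0.9), ("X", "Y", 0.9)])
        expanded, _ = expand_network(core, ppi)
        assert expanded.graph.has_edge("X", "Y")

    def test_new_node_matching_disease_gene_gets_disease_role(self):
        core = build_disease_network(["A", "B"], edges_df([("A", "B", 0.9)]))
        ppi = edges_df([("A", "D", 0.9)])
        expanded, _ = expand_network(core, ppi, disease_genes=["D"])
        assert expanded.graph.nodes["D"]["role"] == "disease_target"


class TestAccounting:
    def test_increments_recovered_from_printed_totals(self):
        # component totals (nodes, edges) -> incremental report
        assert increment_report((509, 17284), (608, 25173)) == {
            "nodes_added": 99,
            "edges_added": 7889,
        }
        assert increment_report((608, 25173), (2444, 88132)) == {
            "nodes_added": 1836,
            "edges_added": 62959,
        }


class TestSerialization:
    def test_graphml_round_trip_preserves_roles_and_confidence(self, tmp_path):
        drug, disease = toy_nets()
        merged, _ = merge_networks(drug, disease, edges_df([("A", "D", 0.9)]))
        p = tmp_path / "net.graphml"
        merged.to_graphml(p)
        back = TypedNetwork.from_graphml(p)
        assert dict(back.graph.nodes(data="role")) == dict(merged.graph.nodes(data="role"))
        assert back.graph.edges["A", "D"]["confidence"] == 0.9

    def test_sif_output(self, tmp_path):
        net = build_disease_network(["A", "B"], edges_df([("A", "B", 0.9)]))
        p = tmp_path / "net.sif"
        net.to_sif(p)
        assert p.read_text() == "A\tpp\tB\n"
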