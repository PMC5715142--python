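"""Synthetic-data generators: ground truth consistency, calibration, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from netpharm.adme import apply_adme_filter
from netpharm.synthetic import (
    SimulationConfig,
    gen_annotation,
    gen_bipartite_targets,
    gen_compound_table,
    gen_disease_genes,
    gen_planted_ppi,
    gene_symbols,
)


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="pass_fraction"):
            SimulationConfig(pass_fraction=1.5)

    def test_p_out_must_be_below_p_in(self):
        with pytest.raises(ValueError, match="p_out"):
            SimulationConfig(p_in=0.3, p_out=0.3)


class TestCompoundTable:
    def test_pass_fraction_one_all_pass(self):
        table, labels = gen_compound_table(SimulationConfig(seed=1, n_compounds=50, pass_fraction=1.0))
        retained, excluded = apply_adme_filter(table)
        assert len(retained) == 50 and excluded.empty
        assert labels.all()

    def test_pass_fraction_zero_none_pass(self):
        table, labels = gen_compound_table(SimulationConfig(seed=1, n_compounds=50, pass_fraction=0.0))
        retained, _ = apply_adme_filter(table)
        assert retained.empty and not labels.any()

    def test_observed_pass_rate_within_binomial_error(self):
        # n=10000, p=0.3: 3 standard errors = 3*sqrt(p(1-p)/n)
        cfg = SimulationConfig(seed=7, n_compounds=10000, pass_fraction=0.3)
        table, labels = gen_compound_table(cfg)
        retained, _ = apply_adme_filter(table)
        rate = len(retained) / len(table)
        assert abs(rate - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 10000)
        # emitted labels agree exactly with a recount through the filter
        assert set(retained["compound_id"]) == set(labels.index[labels])

    def test_determinism(self):
        a, _ = gen_compound_table(SimulationConfig(seed=11, n_compounds=30))
        b, _ = gen_compound_table(SimulationConfig(seed=11, n_compounds=30))
        pd.testing.assert_frame_equal(a, b)


class TestPlantedPpi:
    def test_full_within_no_between_gives_disjoint_cliques(self):
        cfg = SimulationConfig(seed=3, n_modules=3, module_size=5, p_in=1.0, p_out=0.0)
        edges, labels = gen_planted_ppi(cfg)
        assert len(edges) == 3 * 10  # 3 * C(5,2)
        for row in edges.itertuples(index=False):
            assert labels[row.node_a] == labels[row.node_b]

    def test_within_module_edge_count_binomial_bound(self):
        cfg = SimulationConfig(seed=1, n_modules=3, module_size=8, p_in=0.9, p_out=0.02)
        edges, labels = gen_planted_ppi(cfg)
        within = sum(labels[a] == labels[b] for a, b in zip(edges["node_a"], edges["node_b"]))
        n_pairs = 3 * 28  # 3 modules * C(8,2)
        expected = 0.9 * n_pairs
        assert abs(within - expected) <= 3 * math.sqrt(n_pairs * 0.9 * 0.1)

    def test_simple_graph_and_determinism(self):
        cfg = SimulationConfig(seed=2, n_modules=2, module_size=6, p_in=0.8, p_out=0.1)
        e1, _ = gen_planted_ppi(cfg)
        e2, _ = gen_planted_ppi(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        assert (e1["node_a"] < e1["node_b"]).all()  # canonical, hence no self-loops
        assert not e1.duplicated(["node_a", "node_b"]).any()
        assert e1["confidence"].between(0, 1).all()

    def test_module_size_below_three_rejected(self):
        with pytest.raises(ValueError, match="module_size"):
            gen_planted_ppi(SimulationConfig(module_size=2))


class TestBipartite:
    def test_density_one_is_complete(self):
        cfg = SimulationConfig(seed=1, bipartite_density=1.0)
        rows = gen_bipartite_targets(["c1", "c2"], ["g1", "g2", "g3"], cfg)
        assert len(rows) == 6 and not rows.duplicated().any()

    def test_density_zero_is_empty(self):
        cfg = SimulationConfig(seed=1, bipartite_density=0.0)
        assert gen_bipartite_targets(["c1"], ["g1"], cfg).empty

    def test_paper_scale_row_count_binomial_bound(self):
        cfg = SimulationConfig(seed=3, bipartite_density=0.52)
        rows = gen_bipartite_targets(
            [f"c{i}" for i in range(77)], gene_symbols(432), cfg
        )
        n_pairs = 77 * 432
        assert abs(len(rows) - 0.52 * n_pairs) <= 3 * math.sqrt(n_pairs * 0.52 * 0.48)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gen_bipartite_targets([], ["g1"], SimulationConfig())


class TestAnnotation:
    def test_infinite_strength_equals_module_gene_set(self):
        genes = gene_symbols(100)
        labels = {g: (0 if i < 10 else 1) for i, g in enumerate(genes)}
        cfg = SimulationConfig(seed=5, n_terms=3, planted_terms=(("P1", 0, math.inf),))
        terms, truth = gen_annotation(genes, cfg, labels)
        assert truth == {"P1": 0}
        assert terms["P1"][1] == frozenset(g for g, m in labels.items() if m == 0)

    def test_unknown_module_rejected(self):
        cfg = SimulationConfig(seed=5, planted_terms=(("P1", 9, 2.0),))
        with pytest.raises(ValueError, match="unknown module"):
            gen_annotation(gene_symbols(10), cfg, {"G0001": 0})

    def test_background_terms_nonempty_and_deterministic(self):
        genes = gene_symbols(200)
        cfg = SimulationConfig(seed=8, n_terms=20)
        t1, _ = gen_annotation(genes, cfg)
        t2, _ = gen_annotation(genes, cfg)
        assert t1 == t2
        assert len(t1) == 20
        assert all(ts for _, ts in t1.values())


class TestDiseaseGenes:
    def test_zero_overlap_disjoint(self):
        genes = gene_symbols(300)
        targets = genes[:100]
        cfg = SimulationConfig(seed=2, disease_overlap_fraction=0.0, n_disease_genes=50)
        disease, shared = gen_disease_genes(genes, targets, cfg)
        assert not set(disease) & set(targets) and not shared

    def test_full_overlap_subset_of_targets(self):
        genes = gene_symbols(300)
        targets = genes[:100]
        cfg = SimulationConfig(seed=2, disease_overlap_fraction=1.0, n_disease_genes=50)
        disease, shared = gen_disease_genes(genes, targets, cfg)
        assert set(disease) <= set(targets) and shared == frozenset(disease)

    def test_overlap_within_binomial_error(self):
        genes = gene_symbols(1000)
        targets = genes[:400]
        cfg = SimulationConfig(seed=11, disease_overlap_fraction=0.5, n_disease_genes=131)
        disease, shared = gen_disease_genes(genes, targets, cfg)
        assert len(disease) == 131
        observed = len(set(disease) & set(targets))
        assert observed == len(shared)  # ground truth consistent by recount
        assert abs(observed - 65.5) <= 3 * math.sqrt(131 * 0.25)

    def test_oversized_request_rejected(self):
        cfg = SimulationConfig(seed=1, n_disease_genes=20)
        with pytest.raises(ValueError, match="universe"):
            gen_disease_genes(gene_symbols(10), [], cfg)
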