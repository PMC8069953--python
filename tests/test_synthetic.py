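"""Determinism and statistical structure of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from dmdnet.signature import GeneSignature
from dmdnet.synthetic import (
    SyntheticTruth,
    gene_names,
    generate_disease_genes,
    generate_drug_gene_table,
    generate_expression_studies,
    generate_interactome,
    generate_signature_library,
)


class TestExpressionGenerator:
    def test_seeded_determinism(self):
        a, ta = generate_expression_studies(n_studies=3, n_genes=200, seed=7)
        b, tb = generate_expression_studies(n_studies=3, n_genes=200, seed=7)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.matrix, sb.matrix)
        assert ta.deg_genes_up == tb.deg_genes_up

    def test_null_generator_has_empty_truth(self):
        _, truth = generate_expression_studies(n_genes=100, deg_fraction=0.0, seed=1)
        assert truth.deg_genes_up == set() and truth.deg_genes_down == set()

    def test_planted_genes_shifted_consistently(self):
        studies, truth = generate_expression_studies(
            n_studies=2, n_genes=300, deg_fraction=0.1, effect_magnitude=3.0,
            panel_fraction=(1.0, 1.0), seed=3,
        )
        for study in studies:
            case = study.matrix.loc[:, study.groups == "case"]
            ctrl = study.matrix.loc[:, study.groups == "control"]
            diff = case.mean(axis=1) - ctrl.mean(axis=1)
            assert diff.loc[sorted(truth.deg_genes_up)].mean() > 2
            assert diff.loc[sorted(truth.deg_genes_down)].mean() < -2

    def test_explicit_planted_lists(self):
        studies, truth = generate_expression_studies(
            n_genes=100, planted_up=["G00001"], planted_down=["G00002"], seed=0
        )
        assert truth.deg_genes_up == {"G00001"}
        assert truth.deg_genes_down == {"G00002"}
        with pytest.raises(ValueError, match="outside the universe"):
            generate_expression_studies(n_genes=10, planted_up=["G99999"], seed=0)

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="2 samples"):
            generate_expression_studies(n_cases=1, seed=0)
        with pytest.raises(ValueError, match="deg_fraction"):
            generate_expression_studies(deg_fraction=1.5, seed=0)


class TestInteractomeGenerator:
    def test_edge_count_by_construction(self):
        net = generate_interactome(1000, 3, seed=0)
        assert net.number_of_edges() == (1000 - 3) * 3

    def test_seeded_determinism(self):
        a = generate_interactome(200, 3, seed=5)
        b = generate_interactome(200, 3, seed=5)
        assert sorted(a.edges) == sorted(b.edges)

    @pytest.mark.parametrize("seed", range(20))
    def test_heavy_tailed_degrees(self, seed):
        net = generate_interactome(1000, 3, seed=seed)
        degrees = np.array([d for _, d in net.degree()])
        assert degrees.max() > 10 * np.median(degrees)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError, match="n_nodes"):
            generate_interactome(3, 3, seed=0)


class TestDiseaseGeneGenerator:
    def test_local_module_is_connected(self, ba_graph):
        import networkx as nx

        module = generate_disease_genes(ba_graph, module_size=40, locality=1.0, seed=2)
        assert len(module) == 40
        assert nx.is_connected(ba_graph.subgraph(module))

    def test_singleton_and_size_errors(self, ba_graph):
        assert len(generate_disease_genes(ba_graph, module_size=1, seed=0)) == 1
        with pytest.raises(ValueError, match="module_size"):
            generate_disease_genes(ba_graph, module_size=2000, seed=0)

    def test_seeded_determinism(self, ba_graph):
        a = generate_disease_genes(ba_graph, module_size=30, locality=0.5, seed=9)
        b = generate_disease_genes(ba_graph, module_size=30, locality=0.5, seed=9)
        assert a == b


class TestDrugTableGenerator:
    def test_seeded_determinism(self):
        sig = GeneSignature(up=set(gene_names(100)[:10]))
        a, _ = generate_drug_gene_table(gene_names(100), n_drugs=20, signature=sig,
                                        planted_reversers=2, seed=4)
        b, _ = generate_drug_gene_table(gene_names(100), n_drugs=20, signature=sig,
                                        planted_reversers=2, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_delegation_identity(self):
        """A planted drug whose targets all fall in the signature scores
        exactly the closed-form overlap tail."""
        from dmdnet.drug_enrichment import enrich_drugs
        from dmdnet.stats import hypergeom_tail

        universe = gene_names(10575)
        sig = GeneSignature(up=set(universe[:72]))
        records = pd.DataFrame(
            [("dplanted", g, "inhibitor") for g in universe[:3]],
            columns=["drug", "gene", "interaction_types"],
        )
        result = enrich_drugs(records, sig.up, set(universe), signature=sig)
        assert result.loc[0, "p"] == pytest.approx(hypergeom_tail(10575, 72, 3, 3))

    def test_reverser_pairs_oppose_signature(self):
        from dmdnet.drug_enrichment import classify_interaction

        universe = gene_names(200)
        sig = GeneSignature(up=set(universe[:20]), down=set(universe[20:40]))
        table, truth = generate_drug_gene_table(
            universe, n_drugs=10, signature=sig, planted_reversers=3,
            planted_hits=8, seed=6,
        )
        planted = table[table["drug_name"].isin(truth.reversing_drugs)]
        in_sig = planted[planted["gene_name"].isin(sig.genes)]
        for gene, types in zip(in_sig["gene_name"], in_sig["interaction_types"]):
            cls = classify_interaction(types)
            if gene in sig.up:
                assert cls == "inhibiting"
            else:
                assert cls == "activating"

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="empty"):
            generate_drug_gene_table([], seed=0)
        with pytest.raises(ValueError, match="planted_reversers"):
            generate_drug_gene_table(gene_names(10), n_drugs=2, planted_reversers=3,
                                     signature=GeneSignature(up={"G00001"}), seed=0)


class TestTruthSerialization:
    def test_json_round_trip(self, tmp_path):
        truth = SyntheticTruth(
            deg_genes_up={"G00001"}, deg_genes_down={"G00002"},
            module_genes={"G00003"}, reversing_drugs={"DRUG0001"}, rng_seed=5,
        )
        truth.to_json(tmp_path / "t.json")
        assert SyntheticTruth.from_json(tmp_path / "t.json") == truth

    def test_library_generator_determinism(self):
        a, _ = generate_signature_library(gene_names(100), n_signatures=5, seed=8)
        b, _ = generate_signature_library(gene_names(100), n_signatures=5, seed=8)
        assert a == b
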