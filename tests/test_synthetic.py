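"""Generator contracts: determinism, planted structure, moment checks."""

import math

import networkx as nx
import numpy as np
import pytest

from srbmine.annotate import GeneDictionary
from srbmine.synthetic import (
    PATHWAYS,
    ComponentSpec,
    SimulationConfig,
    generate_corpus,
    generate_gene_dictionary,
    generate_pangenome,
    generate_ppi_network,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_docs": -1},
            {"decoy_rate": 1.5},
            {"cluster_density": -0.1},
            {"background_density": 2.0},
            {"pathway_quotas": (1, 1, 1, 1, 1, 1), "n_genes": 20},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_mixture_weights_must_sum_to_one(self):
        spec = (
            ComponentSpec("persistent", 0.6, p=0.95),
            ComponentSpec("cloud", 0.3, p=0.05),
        )
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(mixture_spec=spec)


class TestGeneDictionary:
    def test_pathway_quotas_give_exact_census(self):
        cfg = SimulationConfig(
            seed=3, n_genes=20, pathway_quotas=(8, 1, 1, 3, 5, 2)
        )
        d = generate_gene_dictionary(cfg)
        census = {p: 0 for p in PATHWAYS}
        for rec in d.records.values():
            census[rec.pathway] += 1
        assert [census[p] for p in PATHWAYS] == [8, 1, 1, 3, 5, 2]

    def test_locus_tag_pattern_and_record_shape(self):
        d = generate_gene_dictionary(SimulationConfig(seed=1, n_genes=30))
        assert len(d) == 30
        for tag, rec in d.records.items():
            assert tag.startswith("dde_") and len(tag) == 8 and tag[4:].isdigit()
            assert rec.symbol
            assert 0 <= len(rec.synonyms) <= 3
            assert rec.pathway in PATHWAYS
            assert len(rec.go_terms) >= 1
            assert all(a in (
                "molecular_function", "biological_process", "cellular_component"
            ) for _, a in rec.go_terms)

    def test_same_seed_is_byte_identical(self):
        a = generate_gene_dictionary(SimulationConfig(seed=5))
        b = generate_gene_dictionary(SimulationConfig(seed=5))
        assert a.records == b.records and a.lookup == b.lookup

    def test_single_gene(self):
        d = generate_gene_dictionary(SimulationConfig(seed=0, n_genes=1))
        assert len(d) == 1


class TestCorpus:
    def test_zero_mention_rate_gives_empty_gold(self):
        cfg = SimulationConfig(seed=1, n_genes=10, n_docs=5, mention_rate=0.0)
        docs, truth = generate_corpus(generate_gene_dictionary(cfg), cfg)
        assert all(not d.mentions for d in docs)

    def test_gold_mention_total_matches_poisson_moment(self):
        # 50 docs x rate 4 => 200 expected, SE = sqrt(200)
        cfg = SimulationConfig(seed=11, n_docs=50, mention_rate=4.0)
        docs, _ = generate_corpus(generate_gene_dictionary(cfg), cfg)
        total = sum(len(d.mentions) for d in docs)
        assert abs(total - 200) <= 3 * math.sqrt(200)

    def test_gold_spans_slice_back_to_mention_text(self, small_config):
        docs, _ = generate_corpus(
            generate_gene_dictionary(small_config), small_config
        )
        for doc in docs:
            for m in doc.mentions:
                assert doc.text[m.start : m.end] == m.text

    def test_decoys_and_fillers_never_match_the_dictionary(self, small_config):
        # re-annotating a generated document recovers exactly the gold spans:
        # decoys are rejection-sampled against the lookup and filler words
        # never collide with generated surfaces
        from srbmine.annotate import annotate_document

        d = generate_gene_dictionary(small_config)
        docs, _ = generate_corpus(d, small_config)
        for doc in docs:
            found = annotate_document(doc.doc_id, doc.text, d)
            assert [(m.start, m.end, m.locus_tag) for m in found.mentions] == [
                (m.start, m.end, m.locus_tag) for m in doc.mentions
            ]

    def test_empty_dictionary_rejected(self, small_config):
        empty = GeneDictionary(records={}, lookup={})
        with pytest.raises(ValueError, match="empty"):
            generate_corpus(empty, small_config)


class TestPpiNetwork:
    def test_extreme_densities_give_pathway_cliques(self):
        cfg = SimulationConfig(
            seed=2, n_genes=18, cluster_density=1.0, background_density=0.0
        )
        d = generate_gene_dictionary(cfg)
        g = generate_ppi_network(d, cfg)
        comps = list(nx.connected_components(g))
        for comp in comps:
            pathways = {d.records[n].pathway for n in comp}
            assert len(pathways) == 1  # each component is one pathway clique
            k = len(comp)
            assert g.subgraph(comp).number_of_edges() == k * (k - 1) // 2

    def test_edge_count_matches_binomial_moment(self):
        cfg = SimulationConfig(seed=9, n_genes=60)
        d = generate_gene_dictionary(cfg)
        g = generate_ppi_network(d, cfg)
        sizes = {}
        for rec in d.records.values():
            sizes[rec.pathway] = sizes.get(rec.pathway, 0) + 1
        within = sum(n * (n - 1) // 2 for n in sizes.values())
        total = cfg.n_genes * (cfg.n_genes - 1) // 2
        cross = total - within
        mean = cfg.cluster_density * within + cfg.background_density * cross
        var = (
            cfg.cluster_density * (1 - cfg.cluster_density) * within
            + cfg.background_density * (1 - cfg.background_density) * cross
        )
        assert abs(g.number_of_edges() - mean) <= 3 * math.sqrt(var)

    def test_scores_in_unit_interval_and_deterministic(self, small_config):
        d = generate_gene_dictionary(small_config)
        g1 = generate_ppi_network(d, small_config)
        g2 = generate_ppi_network(d, small_config)
        assert set(g1.edges) == set(g2.edges)
        for a, b in g1.edges:
            for key in ("combined_score", "textmining_score", "experimental_score"):
                assert 0.0 <= g1[a][b][key] <= 1.0
                assert g1[a][b][key] == g2[a][b][key]


class TestPangenome:
    def test_degenerate_cloud_rows_all_zero(self):
        spec = (
            ComponentSpec("persistent", 0.5, p=0.98),
            ComponentSpec("cloud", 0.5, p=0.0),
        )
        cfg = SimulationConfig(seed=4, n_families=100, mixture_spec=spec)
        matrix, _, truth = generate_pangenome(cfg)
        for fam, label in truth.family_labels.items():
            if label == "cloud":
                assert matrix.loc[fam].sum() == 0

    def test_persistent_row_sum_moment(self):
        # p=0.98, 40 genomes => mean 39.2, per-row var = 40*.98*.02
        cfg = SimulationConfig(seed=8)
        matrix, _, truth = generate_pangenome(cfg)
        rows = [f for f, l in truth.family_labels.items() if l == "persistent"]
        sums = matrix.loc[rows].sum(axis=1)
        se = math.sqrt(40 * 0.98 * 0.02 / len(rows))
        assert abs(sums.mean() - 39.2) <= 3 * se

    def test_zero_contiguity_prob_gives_edgeless_graph(self):
        cfg = SimulationConfig(seed=4, n_families=50, contiguity_prob=0.0)
        _, graph, _ = generate_pangenome(cfg)
        assert graph.number_of_edges() == 0

    def test_component_frequencies_converge_to_weights(self):
        cfg = SimulationConfig(seed=13, n_families=2000)
        _, _, truth = generate_pangenome(cfg)
        labels = list(truth.family_labels.values())
        for comp in cfg.mixture_spec:
            freq = labels.count(comp.label) / len(labels)
            se = math.sqrt(comp.weight * (1 - comp.weight) / len(labels))
            assert abs(freq - comp.weight) <= 3 * se

    def test_identical_mean_components_rejected(self):
        spec = (
            ComponentSpec("a", 0.5, p=0.5),
            ComponentSpec("b", 0.5, p=0.5),
        )
        with pytest.raises(ValueError, match="distinct"):
            generate_pangenome(SimulationConfig(seed=0, mixture_spec=spec))

    def test_determinism(self):
        m1, g1, t1 = generate_pangenome(SimulationConfig(seed=21))
        m2, g2, t2 = generate_pangenome(SimulationConfig(seed=21))
        assert m1.equals(m2)
        assert set(g1.edges) == set(g2.edges)
        assert t1.family_labels == t2.family_labels
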