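"""Synthetic scenario generator: determinism and planted ground truth."""

import networkx as nx
import numpy as np
import pytest

from netprox import (
    ValidationError,
    closest_distance,
    generate_annotations,
    generate_compound_cohorts,
    generate_interactome,
    generate_scenario,
    multi_source_shortest_paths,
    plant_disease_module,
)


class TestInteractomeGenerator:
    def test_edge_count_follows_growth_rule(self):
        g = generate_interactome(10, 2, seed=0)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 2 * (10 - 2)
        assert nx.is_connected(g)

    def test_same_seed_reproduces_edge_set(self):
        a = generate_interactome(50, 3, seed=5)
        b = generate_interactome(50, 3, seed=5)
        assert set(a.edges) == set(b.edges)

    def test_attachment_one_yields_tree(self):
        g = generate_interactome(30, 1, seed=1)
        assert g.number_of_edges() == 29
        assert nx.is_tree(g)

    def test_undersized_graph_rejected(self):
        with pytest.raises(ValidationError):
            generate_interactome(3, 3, seed=0)


class TestDiseaseModule:
    def test_singleton_module(self):
        g = generate_interactome(20, 2, seed=0)
        m = plant_disease_module(g, 1, seed=0)
        assert len(m.proteins) == 1

    def test_whole_graph_module(self):
        g = generate_interactome(15, 2, seed=0)
        m = plant_disease_module(g, 15, seed=0)
        assert m.proteins == set(g.nodes)

    @pytest.mark.parametrize("seed", range(5))
    def test_module_induces_connected_subgraph(self, seed):
        g = generate_interactome(100, 3, seed=seed)
        m = plant_disease_module(g, 12, seed=seed)
        assert len(m.proteins) == 12
        assert nx.is_connected(g.subgraph(m.proteins))

    def test_oversized_module_rejected(self):
        g = generate_interactome(10, 2, seed=0)
        with pytest.raises(ValidationError):
            plant_disease_module(g, 11, seed=0)


class TestCompoundCohorts:
    def test_radius_zero_targets_subset_of_module(self):
        g = generate_interactome(300, 3, seed=2)
        m = plant_disease_module(g, 25, seed=2)
        compounds, _ = generate_compound_cohorts(
            g, m, n_proximal=5, n_distal=0,
            targets_per_compound=(3, 8), proximity_radius=0, seed=2,
        )
        for targets, cohort in compounds.values():
            assert cohort == "proximal"
            assert targets <= m.proteins
            assert closest_distance(m.proteins, targets, g) == 0.0

    def test_proximal_targets_within_radius(self):
        g = generate_interactome(300, 3, seed=3)
        m = plant_disease_module(g, 20, seed=3)
        compounds, _ = generate_compound_cohorts(
            g, m, 5, 5, (5, 10), proximity_radius=1, seed=3
        )
        dist = multi_source_shortest_paths(g, m.proteins)
        for targets, cohort in compounds.values():
            ds = [dist[t] for t in targets]
            if cohort == "proximal":
                assert max(ds) <= 1
            else:
                assert min(ds) > 1

    def test_no_proximal_cohort_emits_only_distal(self):
        g = generate_interactome(200, 3, seed=4)
        m = plant_disease_module(g, 10, seed=4)
        compounds, _ = generate_compound_cohorts(g, m, 0, 4, (3, 5), 1, seed=4)
        assert {c for _, c in compounds.values()} == {"distal"}

    def test_scores_straddle_confidence_threshold(self):
        g = generate_interactome(300, 3, seed=5)
        m = plant_disease_module(g, 20, seed=5)
        compounds, scores = generate_compound_cohorts(g, m, 8, 8, (5, 10), 1, seed=5)
        prox_scores = [
            s for (c, _), s in scores.items() if compounds[c][1] == "proximal"
        ]
        dist_scores = [
            s for (c, _), s in scores.items() if compounds[c][1] == "distal"
        ]
        assert all(0.82 <= s <= 1.0 for s in prox_scores)
        assert all(0.5 <= s <= 0.95 for s in dist_scores)
        assert any(s <= 0.82 for s in dist_scores)  # filter has something to cut


class TestAnnotations:
    def test_enriched_set_equal_to_universe_carries_no_signal(self):
        g = generate_interactome(100, 2, seed=6)
        m = plant_disease_module(g, 10, seed=6)
        terms = generate_annotations(
            g, m, n_terms=3, term_size_range=(10, 20),
            enrich_first_term_in=set(g.nodes), seed=6,
        )
        assert len(terms) == 3
        # with uniform weights the first term is just another random subset
        assert all(t <= set(g.nodes) for t in terms.values())

    def test_first_term_oversamples_enrichment_set(self):
        g = generate_interactome(500, 3, seed=7)
        m = plant_disease_module(g, 30, seed=7)
        hits = []
        for s in range(20):
            terms = generate_annotations(
                g, m, 5, (40, 60), m.proteins, seed=s, enrichment_fold=5.0
            )
            hits.append(len(terms["TERM000"] & m.proteins))
        # baseline expectation is ~50*30/500 = 3 module proteins per term;
        # the 5x weighting should push well above it on average
        assert np.mean(hits) > 6

    def test_same_seed_reproduces_terms(self):
        g = generate_interactome(100, 2, seed=8)
        m = plant_disease_module(g, 10, seed=8)
        a = generate_annotations(g, m, 4, (5, 15), m.proteins, seed=9)
        b = generate_annotations(g, m, 4, (5, 15), m.proteins, seed=9)
        assert a == b

    def test_infeasible_sizes_rejected(self):
        g = generate_interactome(20, 2, seed=0)
        m = plant_disease_module(g, 5, seed=0)
        with pytest.raises(ValidationError):
            generate_annotations(g, m, 2, (25, 30), m.proteins, seed=0)


class TestScenario:
    def test_regeneration_is_bit_identical(self):
        a = generate_scenario(seed=42, n_nodes=150, module_size=10,
                              n_proximal=3, n_distal=3,
                              targets_per_compound=(4, 8))
        b = generate_scenario(seed=42, n_nodes=150, module_size=10,
                              n_proximal=3, n_distal=3,
                              targets_per_compound=(4, 8))
        assert set(a.interactome.edges) == set(b.interactome.edges)
        assert a.disease_module.proteins == b.disease_module.proteins
        assert a.disease_module.process_group == b.disease_module.process_group
        assert a.compounds == b.compounds
        assert a.scores == b.scores
        assert a.annotations == b.annotations
        assert a.cti_table().equals(b.cti_table())

    def test_every_target_is_an_interactome_node(self, small_scenario):
        nodes = set(small_scenario.interactome.nodes)
        for targets, _ in small_scenario.compounds.values():
            assert targets <= nodes

    def test_module_connected_within_interactome(self, small_scenario):
        sub = small_scenario.interactome.subgraph(
            small_scenario.disease_module.proteins
        )
        assert nx.is_connected(sub)

    def test_written_scenario_files_round_trip(self, tmp_path, small_scenario):
        from netprox import load_edge_list, read_cti_table, read_disease_proteins
        paths = small_scenario.write(tmp_path / "scn")
        g = load_edge_list(paths["interactome"])
        assert set(g.edges) == set(small_scenario.interactome.edges) or (
            g.number_of_edges() == small_scenario.interactome.number_of_edges()
        )
        cti = read_cti_table(paths["cti"])
        assert len(cti) == sum(
            len(t) for t, _ in small_scenario.compounds.values()
        )
        disease = read_disease_proteins(paths["disease"])
        assert disease.proteins == small_scenario.disease_module.proteins
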