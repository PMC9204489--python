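"""Closest distance, degree-matched null, z-scores, and the compound screen."""

import networkx as nx
import numpy as np
import pytest

from netprox import (
    AnalysisError,
    ValidationError,
    build_degree_bins,
    closest_distance,
    degree_matched_sample,
    proximity_zscore,
    reference_distribution,
    screen_compounds,
)
from netprox.cti import make_table

from conftest import brute_closest_distance, random_connected_graph


class TestClosestDistance:
    def test_path_graph_example(self, path5):
        assert closest_distance({"1"}, {"3", "5"}, path5) == pytest.approx(3.0)

    def test_targets_inside_disease_set_give_zero(self, path5):
        assert closest_distance({"1", "2", "3"}, {"2", "3"}, path5) == 0.0

    def test_members_outside_graph_dropped(self, path5):
        d = closest_distance({"1", "ghost"}, {"3", "phantom"}, path5)
        assert d == pytest.approx(2.0)

    def test_empty_after_restriction_raises(self, path5):
        with pytest.raises(AnalysisError, match="disease set S"):
            closest_distance({"ghost"}, {"3"}, path5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_target_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng)
        nodes = sorted(g.nodes)
        S = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
        T = set(rng.choice(nodes, size=int(rng.integers(1, 8)), replace=False))
        assert closest_distance(S, T, g) == pytest.approx(
            brute_closest_distance(g, S, T)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_enlarging_disease_set_never_increases_distance(self, seed):
        rng = np.random.default_rng(50 + seed)
        g = random_connected_graph(rng)
        nodes = sorted(g.nodes)
        S = set(rng.choice(nodes, size=2, replace=False))
        T = set(rng.choice(nodes, size=5, replace=False))
        extra = S | set(rng.choice(nodes, size=3, replace=False))
        assert closest_distance(extra, T, g) <= closest_distance(S, T, g) + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_removing_farthest_target_never_increases_distance(self, seed):
        rng = np.random.default_rng(80 + seed)
        g = random_connected_graph(rng)
        nodes = sorted(g.nodes)
        S = {nodes[0]}
        size = min(5, len(nodes) - 1)
        T = set(rng.choice(nodes[1:], size=size, replace=False))
        per_target = {t: brute_closest_distance(g, S, {t}) for t in T}
        farthest = max(sorted(T), key=lambda t: per_target[t])
        if len(T) > 1:
            assert closest_distance(S, T - {farthest}, g) <= closest_distance(S, T, g)


class TestDegreeMatchedSample:
    def test_singleton_bin_returns_reference(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, str)
        bins = build_degree_bins(g, min_bin_size=1)
        degree_of = dict(g.degree())
        # node "1" is the unique degree-2 node: its bin forces itself
        out = degree_matched_sample({"1"}, bins, degree_of, np.random.default_rng(0))
        assert out == {"1"}

    def test_sample_is_size_and_bin_matched(self):
        g = random_connected_graph(np.random.default_rng(3), max_nodes=40)
        bins = build_degree_bins(g, min_bin_size=5)
        degree_of = dict(g.degree())
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(42)
        for _ in range(100):
            ref = set(rng.choice(nodes, size=4, replace=False))
            sample = degree_matched_sample(ref, bins, degree_of, rng)
            assert len(sample) == len(ref)
            ref_bins = sorted(bins.bin_index(degree_of[p]) for p in ref)
            # every sampled protein must come from some reference protein's
            # bin (up to widening, which cannot trigger here: bins >= 5)
            sample_bins = sorted(bins.bin_index(degree_of[p]) for p in sample)
            assert sample_bins == ref_bins

    def test_same_seed_reproduces_and_seeds_differ(self):
        g = random_connected_graph(np.random.default_rng(9), max_nodes=50)
        bins = build_degree_bins(g, min_bin_size=5)
        degree_of = dict(g.degree())
        ref = set(sorted(g.nodes)[:8])
        a = degree_matched_sample(ref, bins, degree_of, np.random.default_rng(5))
        b = degree_matched_sample(ref, bins, degree_of, np.random.default_rng(5))
        c = degree_matched_sample(ref, bins, degree_of, np.random.default_rng(6))
        assert a == b
        assert a != c  # astronomically unlikely to collide

    def test_oversized_reference_rejected(self, path5):
        bins = build_degree_bins(path5, min_bin_size=1)
        degree_of = dict(path5.degree())
        with pytest.raises(ValidationError):
            degree_matched_sample(
                {"1", "2", "3", "4", "5", "6"}, bins, degree_of,
                np.random.default_rng(0),
            )


class TestReferenceDistribution:
    def test_complete_graph_null_is_overlap_fraction(self):
        # On K5 every draw gives d_c = (fraction of T* outside S*); for
        # independent uniform 2-subsets E[d_c] = P(t not in S*) = 3/5.
        g = nx.relabel_nodes(nx.complete_graph(5), str)
        bins = build_degree_bins(g, min_bin_size=1)
        mu, sigma, samples = reference_distribution(
            {"0", "1"}, {"2", "3"}, g, bins, 2000, np.random.default_rng(0)
        )
        assert set(samples) <= {0.0, 0.5, 1.0}
        assert mu == pytest.approx(0.6, abs=0.04)
        assert sigma >= 0

    def test_cycle_null_mean_is_average_pair_distance(self):
        # All C6 nodes are degree-2, so sampling is uniform over nodes and
        # the null mean approaches the mean distance over ordered pairs
        # (0+1+2+3+2+1)/6 = 1.5.
        g = nx.relabel_nodes(nx.cycle_graph(6), str)
        bins = build_degree_bins(g, min_bin_size=1)
        mu, _, _ = reference_distribution(
            {"0"}, {"3"}, g, bins, 3000, np.random.default_rng(1)
        )
        assert mu == pytest.approx(1.5, abs=0.08)

    def test_degenerate_null_has_zero_sigma(self):
        # S covers the whole of K4, so every draw returns d_c = 0.
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        bins = build_degree_bins(g, min_bin_size=1)
        mu, sigma, _ = reference_distribution(
            set(g.nodes), {"0"}, g, bins, 50, np.random.default_rng(2)
        )
        assert (mu, sigma) == (0.0, 0.0)
        assert proximity_zscore(0.0, mu, sigma) is None

    def test_too_few_iterations_rejected(self, path5):
        bins = build_degree_bins(path5, min_bin_size=1)
        with pytest.raises(ValidationError):
            reference_distribution({"1"}, {"3"}, path5, bins, 1, np.random.default_rng(0))


class TestZScore:
    def test_arithmetic(self):
        assert proximity_zscore(1.0, 2.0, 0.5) == pytest.approx(-2.0)

    def test_distance_at_null_mean_scores_zero(self):
        assert proximity_zscore(1.7, 1.7, 0.3) == 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            proximity_zscore(1.0, 1.0, -0.1)


class TestScreen:
    def test_planted_ordering_and_zero_distance(self, small_scenario):
        g = small_scenario.interactome
        module = small_scenario.disease_module
        inside = sorted(module.proteins)[:3]
        far_pool = sorted(set(g.nodes) - module.proteins)
        cti = make_table(
            [("inside", t, "inhibitory", "predicted", 0.9) for t in inside]
            + [("outside", t, "inhibitory", "predicted", 0.9) for t in far_pool[-3:]]
        )
        results = screen_compounds(
            cti, module, g, n_iterations=50, min_bin_size=20, seed=0
        )
        assert results[0].compound_id == "inside"
        assert results[0].d_c == 0.0
        assert results[0].n_direct_interactions == 3

    def test_single_compound_gives_single_row(self, small_scenario):
        g = small_scenario.interactome
        cti = make_table(
            [("only", sorted(g.nodes)[10], "inhibitory", "predicted", 0.9)]
        )
        res = screen_compounds(
            cti, small_scenario.disease_module, g,
            n_iterations=20, min_bin_size=20, seed=1,
        )
        assert len(res) == 1

    def test_identical_inputs_and_seed_reproduce_bit_identically(self, small_scenario):
        cti = small_scenario.cti_table()
        kwargs = dict(n_iterations=30, min_bin_size=20, seed=123)
        a = screen_compounds(
            cti, small_scenario.disease_module, small_scenario.interactome, **kwargs
        )
        b = screen_compounds(
            cti, small_scenario.disease_module, small_scenario.interactome, **kwargs
        )
        assert a == b

    def test_empty_table_rejected(self, small_scenario):
        with pytest.raises(ValidationError):
            screen_compounds(
                make_table([]), small_scenario.disease_module,
                small_scenario.interactome,
            )

    def test_targets_outside_network_counted(self, small_scenario):
        g = small_scenario.interactome
        t_in = sorted(small_scenario.disease_module.proteins)[0]
        cti = make_table([
            ("c", t_in, "inhibitory", "predicted", 0.9),
            ("c", "NOT_A_NODE", "inhibitory", "predicted", 0.9),
        ])
        res = screen_compounds(
            cti, small_scenario.disease_module, g,
            n_iterations=20, min_bin_size=20, seed=0,
        )
        assert res[0].n_targets_used == 1
        assert res[0].n_targets_dropped == 1
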