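"""Synthetic graph families: constructions, seeds, and planted guarantees."""

import numpy as np
import pytest

from cliquekit import (
    PlantedSpec,
    brute_force_maximal,
    brute_force_maximum,
    degree_weighted_random,
    enumerate_maximal,
    essential_set,
    gnp_random,
    moon_moser,
    planted_overlap,
    power_law_degrees,
    satellite_graph,
)
from cliquekit.graph import GraphError


class TestMoonMoser:
    def test_single_part_is_three_isolated_vertices(self):
        G = moon_moser(1)
        assert (G.n, G.m) == (3, 0)
        assert len(brute_force_maximal(G)) == 3

    @pytest.mark.parametrize("q", [2, 3, 4])
    def test_maximal_cliques_are_the_transversals(self, q):
        G = moon_moser(q)
        cliques = brute_force_maximal(G)
        assert len(cliques) == 3**q
        assert all(len(c) == q for c in cliques)

    def test_invalid_part_count(self):
        with pytest.raises(GraphError):
            moon_moser(0)


class TestSatelliteGraph:
    def test_pristine_counts_and_omega(self):
        G = satellite_graph()
        assert (G.n, G.m) == (8, 19)
        k, maximum = brute_force_maximum(G)
        assert k == 5 and len(maximum) == 1

    def test_perturbed_drops_edge_and_omega(self):
        G = satellite_graph(perturbed=True)
        assert G.m == 18 and not G.has_edge("1", "2")
        k, maximum = brute_force_maximum(G)
        assert k == 4 and len(maximum) == 4


class TestPlantedOverlap:
    SPEC = PlantedSpec(n=24, clique_size=7, num_cliques=3, core_size=4,
                       background_p=0.05, seed=1)

    def test_planted_cliques_are_exactly_the_maximum_cliques(self):
        G, planted = planted_overlap(self.SPEC)
        _, maximum = brute_force_maximum(G)
        assert maximum.as_set() == planted.as_set()
        assert planted.uniform_size == 7

    def test_cliques_share_exactly_the_core(self):
        _, planted = planted_overlap(self.SPEC)
        cliques = list(planted)
        core = frozenset.intersection(*cliques)
        assert len(core) == self.SPEC.core_size
        for i, a in enumerate(cliques):
            for b in cliques[i + 1 :]:
                assert a & b == core

    def test_single_planted_clique_is_the_essential_set(self):
        spec = PlantedSpec(n=20, clique_size=6, num_cliques=1, core_size=0,
                           background_p=0.08, seed=5)
        G, planted = planted_overlap(spec)
        assert essential_set(G).essential == next(iter(planted))

    def test_zero_background_gives_exactly_planted_edges(self):
        spec = PlantedSpec(n=20, clique_size=5, num_cliques=2, core_size=2,
                           background_p=0.0, seed=3)
        G, planted = planted_overlap(spec)
        expected = sum(len(c) * (len(c) - 1) // 2 for c in planted)
        shared = spec.core_size * (spec.core_size - 1) // 2
        assert G.m == expected - shared
        assert brute_force_maximum(G)[0] == 5

    def test_reproducible_for_fixed_seed(self):
        g1, _ = planted_overlap(self.SPEC)
        g2, _ = planted_overlap(self.SPEC)
        assert g1 == g2

    def test_invalid_spec_rejected(self):
        with pytest.raises(GraphError):
            PlantedSpec(n=5, clique_size=6, num_cliques=1, core_size=0,
                        background_p=0.0, seed=0)
        with pytest.raises(GraphError):
            PlantedSpec(n=10, clique_size=4, num_cliques=4, core_size=0,
                        background_p=0.0, seed=0)  # needs 16 > 10 vertices


class TestDegreeWeightedRandom:
    def test_zero_degrees_give_empty_graph(self):
        assert degree_weighted_random([0, 0, 0], seed=1).m == 0

    def test_negative_degree_rejected(self):
        with pytest.raises(GraphError):
            degree_weighted_random([1, -1], seed=1)

    def test_overweight_degree_rejected(self):
        with pytest.raises(GraphError):
            degree_weighted_random([10, 1, 1], seed=1)  # 100 > 12

    def test_uniform_degrees_match_expected_edge_count(self):
        # all degrees d: every pair has probability d/n; check a 4-sigma band
        n, d = 60, 6
        expected = (n * (n - 1) / 2) * (d / n)
        sigma = np.sqrt((n * (n - 1) / 2) * (d / n) * (1 - d / n))
        counts = [degree_weighted_random([d] * n, seed=s).m for s in range(20)]
        assert abs(np.mean(counts) - expected) < 4 * sigma
        for c in counts:
            assert abs(c - expected) < 6 * sigma

    def test_reproducible_for_fixed_seed(self):
        d = [3] * 30
        assert degree_weighted_random(d, seed=9) == degree_weighted_random(d, seed=9)


class TestPowerLawDegrees:
    def test_valid_input_for_chung_lu(self):
        d = power_law_degrees(500, exponent=2.5, d_max=50, seed=0)
        assert d.min() >= 1 and d.max() ** 2 <= d.sum()
        degree_weighted_random(d, seed=0)  # must not raise

    def test_heavy_tail_present(self):
        d = power_law_degrees(500, exponent=2.5, d_max=50, seed=1)
        assert d.max() > 5 * np.median(d)


class TestGnpRandom:
    def test_extreme_probabilities(self):
        assert gnp_random(10, 0.0, seed=0).m == 0
        assert gnp_random(10, 1.0, seed=0).m == 45

    def test_seeded_and_deterministic(self):
        assert gnp_random(15, 0.4, seed=3) == gnp_random(15, 0.4, seed=3)
        assert gnp_random(15, 0.4, seed=3) != gnp_random(15, 0.4, seed=4)


class TestBruteForceOracle:
    def test_guard_above_25_vertices(self):
        with pytest.raises(ValueError, match="n <= 25"):
            brute_force_maximal(gnp_random(26, 0.1, seed=0))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_backtracking(self, seed):
        G = gnp_random(13, 0.5, seed=1100 + seed)
        assert brute_force_maximal(G) == enumerate_maximal(G).cliques
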