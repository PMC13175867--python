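import networkx as nx
import numpy as np
import pytest

from lncprox.interactome import GeneSet, Interactome, build_degree_bins
from lncprox.proximity import (average_module_distance,
                               build_candidate_module, proximity_matrix,
                               proximity_significance,
                               sample_degree_matched_set)

from conftest import random_connected_graph


def brute_force_average_distance(g: Interactome, S, T) -> float:
    """Independent oracle: all-pairs BFS table, then the double mean."""
    apsp = dict(nx.all_pairs_shortest_path_length(g.graph))
    return float(np.mean([np.mean([apsp[s][t] for t in T]) for s in S]))


class TestCandidateModule:
    def test_path_graph(self, path_graph):
        assert build_candidate_module(path_graph, "B").members == {"A", "B", "C"}

    def test_star_center(self, star_graph):
        assert len(build_candidate_module(star_graph, "X")) == 6

    def test_isolated_seed_is_singleton(self):
        g = Interactome([("A", "B")], nodes=["Z"])
        assert build_candidate_module(g, "Z").members == {"Z"}

    def test_absent_seed_suggests_prefix(self, path_graph):
        with pytest.raises(KeyError, match="A"):
            build_candidate_module(path_graph, "AXX")


class TestAverageModuleDistance:
    def test_self_distance_zero(self, path_graph):
        assert average_module_distance(path_graph, {"A"}, {"A"}) == 0.0

    def test_path_endpoints(self, path_graph):
        assert average_module_distance(path_graph, {"A"}, {"C"}) == 2.0

    def test_hand_enumeration_overlapping_sets(self, path_graph):
        # S={A,B}, T={B,C}: d_A = mean(1,2), d_B = mean(0,1) -> D = 1.0
        assert average_module_distance(path_graph, {"A", "B"}, {"B", "C"}) == 1.0

    def test_unmapped_symbols_dropped(self, path_graph):
        assert average_module_distance(path_graph, {"A", "NOPE"}, {"C"}) == 2.0

    def test_all_unmapped_errors(self, path_graph):
        with pytest.raises(ValueError, match="no symbols map"):
            average_module_distance(path_graph, {"NOPE"}, {"C"})

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 51))
            g = random_connected_graph(n, rng)
            nodes = sorted(g.nodes)
            S = set(rng.choice(nodes, size=int(rng.integers(1, min(6, n))),
                               replace=False))
            T = set(rng.choice(nodes, size=int(rng.integers(1, min(8, n))),
                               replace=False))
            assert average_module_distance(g, S, T) == pytest.approx(
                brute_force_average_distance(g, S, T), abs=1e-12)

    def test_monotone_in_added_far_disease_gene(self):
        # adding a disease gene farther than the current D cannot lower D
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = random_connected_graph(int(rng.integers(6, 30)), rng)
            nodes = sorted(g.nodes)
            S = set(rng.choice(nodes, size=3, replace=False))
            T = set(rng.choice(nodes, size=3, replace=False))
            d0 = average_module_distance(g, S, T)
            apsp = dict(nx.all_pairs_shortest_path_length(g.graph))
            far = [u for u in nodes if u not in T
                   and np.mean([apsp[s][u] for s in S]) >= d0]
            if far:
                assert average_module_distance(g, S, T | {far[0]}) >= d0 - 1e-12


class TestDegreeMatchedSampling:
    def test_degree_bins_preserved_every_draw(self):
        rng = np.random.default_rng(1)
        g = random_connected_graph(40, rng)
        bins = build_degree_bins(g, min_bin_size=5)
        S = set(rng.choice(sorted(g.nodes), size=6, replace=False))
        want = sorted(bins.bin_of(s) for s in S)
        for _ in range(200):
            samp = sample_degree_matched_set(bins, S, rng)
            assert len(samp) == len(S)
            assert sorted(bins.bin_of(x) for x in samp) == want

    def test_forced_draw_returns_module(self, star_graph):
        # with per-degree bins and the center alone in its bin, the center
        # must re-draw itself
        bins = build_degree_bins(star_graph, min_bin_size=1)
        out = sample_degree_matched_set(bins, {"X"}, np.random.default_rng(0))
        assert out == {"X"}

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(30, rng)
        bins = build_degree_bins(g, min_bin_size=4)
        S = set(sorted(g.nodes)[:5])
        a = sample_degree_matched_set(bins, S, np.random.default_rng(77))
        b = sample_degree_matched_set(bins, S, np.random.default_rng(77))
        assert a == b

    def test_unassigned_gene_errors(self):
        g = Interactome([("A", "B"), ("B", "C"), ("C", "A")])
        bins = build_degree_bins(g, min_bin_size=1)
        with pytest.raises(KeyError, match="degree-bin assignment"):
            sample_degree_matched_set(bins, {"A", "NOT_IN_GRAPH"},
                                      np.random.default_rng(0))


class TestProximitySignificance:
    def test_p_emp_on_grid_and_fields(self):
        rng = np.random.default_rng(8)
        g = random_connected_graph(60, rng)
        mod = build_candidate_module(g, sorted(g.nodes)[0])
        T = GeneSet("d", frozenset(rng.choice(sorted(g.nodes), 8, replace=False)))
        res = proximity_significance(g, mod, T, n_randomizations=40,
                                     rng_seed=1, min_bin_size=5)
        assert len(res.null_distances) == 40
        grid = {i / 40 for i in range(41)}
        assert res.p_emp in grid
        assert res.p_emp == np.sum(res.null_distances < res.d_obs) / 40
        assert res.below_detection == (res.p_emp == 0.0)
        assert res.detection_threshold == 1 / 40

    def test_below_detection_display(self):
        # planted-close disease set: observed distance beats every null draw
        from lncprox.synth import gen_interactome, plant_disease_gene_set
        g = gen_interactome(500, seed=3)
        hub = max(g.nodes, key=lambda n: (g.degree(n), n))
        mod = build_candidate_module(g, hub)
        ds, _ = plant_disease_gene_set(g, hub, size=15, closeness=3.0, seed=4)
        res = proximity_significance(g, mod, ds, n_randomizations=250,
                                     rng_seed=5, min_bin_size=25)
        assert res.p_emp == 0.0
        assert res.below_detection
        assert res.p_display == "<0.004"
        assert res.p_conservative == 1 / 251

    def test_strict_inequality_ties_not_less(self, path_graph):
        # K3: every node has degree 2, all pairwise distances 1, so every
        # randomized distance ties the observed one -> p_emp = 0 (strict <)
        g = Interactome([("A", "B"), ("B", "C"), ("C", "A")])
        mod = build_candidate_module(g, "A")
        res = proximity_significance(g, mod, GeneSet("t", frozenset({"B"})),
                                     n_randomizations=20, rng_seed=0,
                                     min_bin_size=1)
        assert res.p_emp == 0.0
        assert res.z_score is None  # degenerate null -> undefined z


class TestProximityMatrix:
    def _setup(self):
        from lncprox.synth import gen_interactome, plant_disease_gene_set
        g = gen_interactome(300, seed=9)
        nodes = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
        modules = [build_candidate_module(g, s) for s in nodes[:2]]
        diseases = [plant_disease_gene_set(g, nodes[0], 10, c, seed=i)[0]
                    for i, c in enumerate((0.0, 2.0))]
        diseases = [GeneSet(f"dis{i}", d.members) for i, d in enumerate(diseases)]
        return g, modules, diseases

    def test_single_cell_consistency(self):
        g, modules, diseases = self._setup()
        mat = proximity_matrix(g, modules[:1], diseases[:1],
                               n_randomizations=30, rng_seed=7, min_bin_size=20)
        df = mat.to_dataframe()
        assert len(df) == 1
        cell = mat.cells[(modules[0].seed, diseases[0].name)]
        assert df.loc[0, "p_emp"] == cell.p_emp

    def test_mask_boundary_strictly_greater(self):
        g, modules, diseases = self._setup()
        mat = proximity_matrix(g, modules[:1], diseases[:1],
                               n_randomizations=30, rng_seed=7, min_bin_size=20)
        key = (modules[0].seed, diseases[0].name)
        mat.cells[key].p_emp = 0.051
        assert mat.is_masked(*key)
        mat.cells[key].p_emp = 0.050
        assert not mat.is_masked(*key)

    def test_tsv_byte_identical_across_runs(self, tmp_path):
        g, modules, diseases = self._setup()
        outs = []
        for run in (1, 2):
            p = tmp_path / f"m{run}.tsv"
            proximity_matrix(g, modules, diseases, n_randomizations=25,
                             rng_seed=13, min_bin_size=20).to_tsv(p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_duplicate_candidates_error(self):
        g, modules, diseases = self._setup()
        with pytest.raises(ValueError, match="duplicate"):
            proximity_matrix(g, [modules[0], modules[0]], diseases,
                             n_randomizations=5, rng_seed=1, min_bin_size=20)
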