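"""The guided walk engine: routing, target selection, tallies."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from fibropath import netbuild, pathsig, pathwalks


def _graph(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestShortestPath:
    def test_src_equals_dst(self):
        g = _graph([("A", "B", 1.0)])
        assert pathwalks.shortest_path(g, "A", "A") == ["A"]

    def test_heavy_detour_beats_light_direct_edge(self):
        # inverse-weight costs: direct A-B costs 1, A-C-B costs 0.2
        g = _graph([("A", "B", 1.0), ("A", "C", 10.0), ("C", "B", 10.0)])
        assert pathwalks.shortest_path(g, "A", "B") == ["A", "C", "B"]

    def test_disconnected_pair_returns_none(self):
        g = _graph([("A", "B", 1.0), ("C", "D", 1.0)])
        assert pathwalks.shortest_path(g, "A", "C") is None

    def test_lexicographic_tie_break(self):
        # two equal-cost routes A-B-D and A-C-D; A,B,D is lexicographically
        # smaller
        g = _graph(
            [("A", "B", 1.0), ("B", "D", 1.0), ("A", "C", 1.0), ("C", "D", 1.0)]
        )
        assert pathwalks.shortest_path(g, "A", "D") == ["A", "B", "D"]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        choices = [0.25, 0.5, 1.0, 2.0, 4.0]
        checked = 0
        for _ in range(60):
            n = int(rng.integers(3, 7))
            g = nx.gnp_random_graph(n, 0.7, seed=int(rng.integers(2**31)))
            for a, b in g.edges:
                g[a][b]["weight"] = choices[rng.integers(len(choices))]
            for s, t in combinations(sorted(g.nodes), 2):
                paths = list(nx.all_simple_paths(g, s, t))
                got = pathwalks.shortest_path(g, s, t)
                if not paths:
                    assert got is None
                    continue
                costs = [
                    sum(1.0 / g[a][b]["weight"] for a, b in zip(p, p[1:]))
                    for p in paths
                ]
                lo = min(costs)
                best = min(
                    tuple(p) for p, c in zip(paths, costs) if c <= lo + 1e-12
                )
                assert got == list(best)
                checked += 1
        assert checked > 100


class TestSelectTargetGuided:
    def test_single_gene_single_pathway(self, rng):
        t = pathwalks.select_target_guided({"g1": 2.0}, {"g1": ["P1"]}, rng)
        assert t == "P1"

    def test_strength_proportional_gene_sampling(self, rng):
        strength = {"g1": 3.0, "g2": 1.0}
        membership = {"g1": ["P1"], "g2": ["P2"]}
        n = 10_000
        hits = sum(
            pathwalks.select_target_guided(strength, membership, rng) == "P1"
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.75 * 0.25)
        assert abs(hits - 0.75 * n) < 3 * sigma

    def test_uniform_pathway_choice_within_gene(self, rng):
        n = 10_000
        hits = sum(
            pathwalks.select_target_guided(
                {"g": 1.0}, {"g": ["P1", "P2"]}, rng
            )
            == "P1"
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.25)
        assert abs(hits - 0.5 * n) < 3 * sigma

    def test_gene_without_membership_excluded(self, rng):
        t = pathwalks.select_target_guided(
            {"g1": 100.0, "g2": 0.1}, {"g2": ["P2"]}, rng
        )
        assert t == "P2"

    def test_no_mapped_gene_fails(self, rng):
        with pytest.raises(ValueError):
            pathwalks.select_target_guided({"g1": 1.0}, {}, rng)


class TestRunPathwalks:
    def test_single_iteration_two_nodes_one_visit(self):
        g = _graph([("A", "B", 1.0)])
        wc = pathwalks.run_pathwalks(g, None, None, 1, "random", seed=0)
        assert wc.total_times_walked == 1

    def test_determinism(self):
        g = _graph([("A", "B", 2.0), ("B", "C", 1.0), ("A", "C", 1.0)])
        a = pathwalks.run_pathwalks(g, None, None, 500, "random", seed=9)
        b = pathwalks.run_pathwalks(g, None, None, 500, "random", seed=9)
        assert a.times_walked == b.times_walked
        assert a.edge_visits == b.edge_visits

    def test_frequencies_sum_to_one(self):
        g = _graph([("A", "B", 1.0), ("B", "C", 3.0), ("C", "D", 2.0)])
        wc = pathwalks.run_pathwalks(g, None, None, 1000, "random", seed=1)
        assert wc.frequencies().sum() == pytest.approx(1.0)

    def test_uniform_on_vertex_transitive_graph(self):
        # odd cycle: antipodal ties would let the deterministic tie-break
        # favor low-numbered nodes; a single run also drifts (consecutive
        # walks share the current node), so pool independent replicates
        g = nx.cycle_graph(9)
        nx.set_edge_attributes(g, 1.0, "weight")
        pooled = None
        for seed in range(10):
            wc = pathwalks.run_pathwalks(g, None, None, 20_000, "random", seed=seed)
            f = wc.frequencies()
            pooled = f if pooled is None else pooled + f
        pooled = pooled / 10
        assert pooled.max() - pooled.min() < 0.02

    def test_walks_confined_to_largest_component(self):
        g = _graph([("A", "B", 1.0), ("B", "C", 1.0), ("X", "Y", 1.0)])
        wc = pathwalks.run_pathwalks(g, None, None, 200, "random", seed=3)
        assert wc.excluded_pathways == ["X", "Y"]
        assert wc.times_walked["X"] == 0 and wc.times_walked["Y"] == 0

    def test_guided_mode_biases_toward_map_genes(self, small_bundle):
        gene_map = netbuild.build_gene_map(small_bundle.functional_records)
        network = netbuild.build_pathway_network(small_bundle.pathways)
        membership = pathwalks.membership_from_pathways(small_bundle.pathways)
        guided = pathwalks.run_pathwalks(
            network, gene_map, membership, 20_000, "guided", seed=4
        )
        random = pathwalks.run_pathwalks(
            network, None, None, 20_000, "random", seed=5
        )
        gf, rf = guided.frequencies(), random.frequencies()
        for p in small_bundle.truth.planted_pathways:
            assert gf[p] > rf[p]

    def test_bad_mode_and_empty_network(self):
        g = _graph([("A", "B", 1.0)])
        with pytest.raises(ValueError):
            pathwalks.run_pathwalks(g, None, None, 10, "levy", seed=0)
        with pytest.raises(ValueError):
            pathwalks.run_pathwalks(nx.Graph(), None, None, 10, "random", 0)


class TestTopPathways:
    def _wc(self, counts):
        return pathwalks.WalkCounts("random", counts, {}, 1, 0)

    def test_ceiling_count(self):
        counts = {f"p{i:03d}": 1 for i in range(100)}
        assert len(pathwalks.top_pathways(self._wc(counts), 0.05)) == 5

    def test_all_equal_ties_resolved_lexically(self):
        counts = {p: 7 for p in ["pB", "pA", "pD", "pC"]}
        assert pathwalks.top_pathways(self._wc(counts), 0.5) == ["pA", "pB"]

    def test_ordering_matches_sort_oracle(self, rng):
        counts = {f"p{i}": int(c) for i, c in enumerate(rng.integers(0, 50, 30))}
        got = pathwalks.top_pathways(self._wc(counts), 1.0)
        expected = [
            p for p, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        assert got == expected


class TestNullTopologyBias:
    def test_random_walks_favor_hubs(self):
        """Visit counts correlate with betweenness + strength in the null."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        g = nx.gnp_random_graph(25, 0.25, seed=17)
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.integers(1, 6))
        largest = max(nx.connected_components(g), key=len)
        g = g.subgraph(largest).copy()
        wc = pathwalks.run_pathwalks(g, None, None, 30_000, "random", seed=6)
        prof = netbuild.topology_profile(g)
        t = prof.table.set_index("pathway")
        score = t["betweenness"].rank() + t["strength"].rank()
        visits = [wc.times_walked[p] for p in t.index]
        rho, _ = spearmanr(visits, score)
        assert rho > 0


class TestConvergence:
    def test_half_run_l1_distance_small(self, small_bundle):
        network = netbuild.build_pathway_network(small_bundle.pathways)
        d = pathwalks.convergence_diagnostic(
            network, None, None, 50_000, "random", seed=0
        )
        assert d < 0.05
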