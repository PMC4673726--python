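import itertools

import numpy as np
import pandas as pd
import networkx as nx
import pytest

from femnet.discovery import (
    FEMDetector,
    FemModule,
    consistency_correlation,
    grow_module,
    module_significance,
    prune_redundant,
    select_seeds,
    validate_modules,
)
from femnet.enrichment import overlap_enrichment
from femnet.network import build_weighted_network, integrated_statistic, modularity
from femnet.simulate import simulate_planted_stats


def _stats_frame(t_D, t_R, genes=None):
    genes = genes or [f"g{i}" for i in range(len(t_D))]
    return pd.DataFrame(
        {"t_D": t_D, "p_D": 0.5, "t_R": t_R, "p_R": 0.5}, index=genes
    )


class TestIntegratedStatistic:
    @pytest.mark.parametrize(
        "t_D,t_R,expected",
        [
            (2.0, -3.0, 5.0),   # anti-correlated: |t_D - t_R|
            (-2.0, 3.0, 5.0),
            (2.0, 3.0, 0.0),    # concordant signs gated to zero
            (-2.0, -3.0, 0.0),
            (0.0, 5.0, 0.0),    # H(0) = 0 boundary convention
            (5.0, 0.0, 0.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_sign_grid(self, t_D, t_R, expected):
        assert integrated_statistic(t_D, t_R) == pytest.approx(expected)

    def test_exhaustive_sign_gating(self):
        for sd, sr in itertools.product([-1, 0, 1], repeat=2):
            t = integrated_statistic(2.5 * sd, 1.5 * sr)
            if sd * sr < 0:
                assert t > 0
            else:
                assert t == 0.0

    def test_vectorised_matches_brute_force(self, rng):
        t_D, t_R = rng.normal(size=100), rng.normal(size=100)
        vec = integrated_statistic(t_D, t_R)
        for i in range(100):
            h = lambda x: 1.0 if x > 0 else 0.0
            brute = (h(t_D[i]) * h(-t_R[i]) + h(-t_D[i]) * h(t_R[i])) * abs(t_D[i] - t_R[i])
            assert vec[i] == pytest.approx(brute, abs=1e-12)


class TestWeightedNetwork:
    def test_edge_weight_is_mean_of_endpoint_statistics(self):
        stats = _stats_frame([5.0, 2.0], [-0.0001, -0.0001], ["a", "b"])
        stats.loc["a", ["t_D", "t_R"]] = [2.5, -2.5]  # t_I = 5
        stats.loc["b", ["t_D", "t_R"]] = [1.0, -1.0]  # t_I = 2
        g = nx.Graph([("a", "b")])
        net = build_weighted_network(stats, g)
        assert net.edges["a", "b"]["weight"] == pytest.approx(3.5)

    def test_zero_statistic_edges_kept_with_zero_weight(self):
        stats = _stats_frame([1.0, 1.0], [2.0, 2.0], ["a", "b"])  # concordant
        net = build_weighted_network(stats, nx.Graph([("a", "b")]))
        assert net.edges["a", "b"]["weight"] == 0.0

    def test_largest_component_kept_with_lexicographic_tie_break(self):
        g = nx.Graph([("b", "c"), ("c", "d"), ("b", "d"), ("e", "f"), ("f", "a"), ("a", "e")])
        stats = _stats_frame([1.0] * 6, [-1.0] * 6, list("abcdef"))
        net = build_weighted_network(stats, g)
        assert set(net.nodes) == {"a", "e", "f"}  # tie of 3 vs 3: keeps 'a'

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="no overlap"):
            build_weighted_network(_stats_frame([1.0], [-1.0], ["zz"]), nx.Graph([("a", "b")]))


class TestModularity:
    def test_mean_of_induced_weights(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("b", "c", weight=2.0)
        g.add_edge("a", "c", weight=3.0)
        assert modularity({"a", "b", "c"}, g) == pytest.approx(2.0)

    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=7.5)
        assert modularity({"a", "b"}, g) == pytest.approx(7.5)

    def test_matches_exhaustive_enumeration_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(0, 5))
            members = list(rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False))
            induced = [
                g.edges[u, v]["weight"]
                for u, v in itertools.combinations(members, 2)
                if g.has_edge(u, v)
            ]
            if not induced:
                with pytest.raises(ValueError):
                    modularity(members, g)
            else:
                assert modularity(members, g) == pytest.approx(float(np.mean(induced)))

    def test_no_induced_edge_is_error(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        nx.set_edge_attributes(g, 1.0, "weight")
        with pytest.raises(ValueError, match="no edges"):
            modularity({"a", "c"}, g)


class TestSeedsAndGrowth:
    def test_top_statistic_seeds_with_lexicographic_ties(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        for n, v in zip("abcd", (5.0, 3.0, 3.0, 1.0)):
            g.nodes[n]["t_I"] = v
        assert select_seeds(g, 2) == ["a", "b"]
        g2 = g.copy()
        nx.set_node_attributes(g2, 1.0, "t_I")
        assert select_seeds(g2, 3) == ["a", "b", "c"]

    def test_truncates_with_warning_when_too_many_requested(self):
        g = nx.Graph([("a", "b")])
        nx.set_node_attributes(g, 1.0, "t_I")
        with pytest.warns(UserWarning, match="truncat"):
            assert select_seeds(g, 10) == ["a", "b"]

    def test_star_with_one_heavy_edge(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
        nx.set_edge_attributes(g, 0.0, "weight")
        g.edges["n0", "n3"]["weight"] = 10.0
        mod = grow_module("n0", g)
        assert set(mod.members) == {"n0", "n3"}
        assert mod.modularity == pytest.approx(10.0)

    def test_isolated_seed_degenerate(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b", weight=1.0)
        mod = grow_module("lonely", g)
        assert mod.size == 1 and mod.p_value == 1.0 and mod.extra.get("degenerate")

    def test_planted_clique_recovered(self, rng):
        """15-gene module with internal weight ~3 against 0.1 background."""
        g = nx.connected_watts_strogatz_graph(120, 6, 0.1, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(120)})
        nx.set_edge_attributes(g, 0.1, "weight")
        members = [f"n{i:03d}" for i in range(15)]
        for u, v in itertools.combinations(members, 2):
            g.add_edge(u, v, weight=float(rng.normal(3.0, 0.1)))
        mod = grow_module(members[3], g)
        got = set(mod.members)
        jac = len(got & set(members)) / len(got | set(members))
        assert jac >= 0.7

    def test_growth_respects_max_size(self):
        g = nx.complete_graph(30)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert grow_module(0, g, max_size=5).size <= 5


class TestSignificance:
    @staticmethod
    def _small_net():
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "c")])
        for n, v in zip("abcde", (5.0, 4.0, 0.5, 0.2, 0.1)):
            g.nodes[n]["t_I"] = v
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.5 * (g.nodes[u]["t_I"] + g.nodes[v]["t_I"])
        return g

    def test_matches_exhaustive_permutation_oracle(self, rng):
        """Sampled permutation p agrees with full enumeration over all 5! node
        assignments (top-statistic module on a 5-node graph)."""
        net = self._small_net()
        mod = FemModule("a", ("a", "b"), modularity({"a", "b"}, net))
        vals = np.array([net.nodes[n]["t_I"] for n in net.nodes])
        names = list(net.nodes)
        ia, ib = names.index("a"), names.index("b")
        observed = 0.5 * (net.nodes["a"]["t_I"] + net.nodes["b"]["t_I"])
        count = sum(
            1
            for perm in itertools.permutations(vals)
            if 0.5 * (perm[ia] + perm[ib]) >= observed - 1e-12
        )
        exact = count / 120
        n_perm = 4000
        p = module_significance(mod, net, n_perm=n_perm, rng=rng)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 4 * se + 2 / n_perm

    def test_relabeling_invariance(self, rng):
        net = self._small_net()
        mod = FemModule("a", ("a", "b", "c"), modularity({"a", "b", "c"}, net))
        p1 = module_significance(mod, net, n_perm=500, rng=np.random.default_rng(5))
        relabel = {n: f"x_{n}" for n in net.nodes}
        net2 = nx.relabel_nodes(net, relabel)
        mod2 = FemModule("x_a", ("x_a", "x_b", "x_c"), mod.modularity)
        p2 = module_significance(mod2, net2, n_perm=500, rng=np.random.default_rng(5))
        assert p1 == p2

    def test_size_one_module_p_is_one(self):
        net = self._small_net()
        assert module_significance(FemModule("a", ("a",), np.nan), net) == 1.0


class TestPruning:
    @staticmethod
    def _mod(seed, members, q):
        return FemModule(seed, tuple(sorted(members)), q)

    def test_identical_modules_deduplicated(self):
        mods = [self._mod("a", "ab", 2.0), self._mod("b", "ab", 1.0)]
        kept = prune_redundant(mods)
        assert len(kept) == 1 and kept[0].seed == "a"

    def test_disjoint_modules_all_kept(self):
        mods = [self._mod("a", "ab", 2.0), self._mod("c", "cd", 1.0)]
        assert len(prune_redundant(mods)) == 2

    def test_nested_module_dropped_by_overlap_coefficient(self):
        small = self._mod("a", "abcde", 1.0)
        big = self._mod("f", "abcdefghij", 2.0)
        kept = prune_redundant([small, big], overlap_threshold=0.5)
        assert [m.seed for m in kept] == ["f"]  # overlap coeff 1 > 0.5

    def test_order_independence_given_modularity_ranking(self, rng):
        mods = [
            self._mod(f"s{i}", rng.choice(list("abcdefghijkl"), size=5, replace=False), float(i))
            for i in range(8)
        ]
        kept1 = [m.seed for m in prune_redundant(list(mods))]
        rng.shuffle(mods)
        kept2 = [m.seed for m in prune_redundant(mods)]
        assert kept1 == kept2


class TestValidationAndConsistency:
    def test_identical_statistics_reproduce_modularity(self, rng):
        stats, net, members = simulate_planted_stats(n_genes=120, module_size=10, seed=2)
        det = FEMDetector(n_seeds=4, n_perm=200, random_state=0).fit(stats, net)
        table = validate_modules(det.modules_, stats, net, n_perm=200, rng=rng)
        for mod in det.modules_:
            assert table.loc[mod.seed, "modularity"] == pytest.approx(mod.modularity)

    def test_zero_statistics_give_zero_modularity_p_one(self, rng):
        stats, net, _ = simulate_planted_stats(n_genes=60, module_size=8, seed=3)
        det = FEMDetector(n_seeds=2, n_perm=100, random_state=0).fit(stats, net)
        null = stats.copy()
        null[["t_D", "t_R"]] = 0.0
        table = validate_modules(det.modules_, null, net, n_perm=100, rng=rng)
        assert (table["modularity"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()

    def test_consistency_correlation_perfect_and_inverted(self):
        stats, _, members = simulate_planted_stats(n_genes=60, module_size=8, seed=4)
        mod = FemModule(members[0], tuple(members), 1.0)
        same = consistency_correlation(stats, stats, mod)
        assert same["r_D"] == pytest.approx(1.0) and same["r_R"] == pytest.approx(1.0)
        flipped = stats.copy()
        flipped[["t_D", "t_R"]] *= -1
        inv = consistency_correlation(stats, flipped, mod)
        assert inv["r_D"] == pytest.approx(-1.0)

    def test_too_few_shared_genes_is_error(self):
        stats, _, members = simulate_planted_stats(n_genes=60, module_size=8, seed=4)
        mod = FemModule(members[0], tuple(members[:2]), 1.0)
        with pytest.raises(ValueError, match="3 shared"):
            consistency_correlation(stats, stats, mod)


class TestEnrichment:
    def test_hypergeometric_hand_value(self):
        universe = {f"u{i}" for i in range(10)}
        gene_set = {"u0", "u1", "u2", "u3", "u4"}
        members = {"u0", "u1", "u2", "u3"}
        out = overlap_enrichment(members, {"S": gene_set}, universe)
        # P(X >= 4) with M=10, K=5, n=4 = C(5,4)C(5,0)/C(10,4) = 5/210
        assert out.loc["S", "p_value"] == pytest.approx(5 / 210)
        assert out.loc["S", "overlap_genes"] == "u0,u1,u2,u3"

    def test_monotone_in_overlap(self):
        universe = {f"u{i}" for i in range(30)}
        gene_set = {f"u{i}" for i in range(10)}
        p = [
            overlap_enrichment(
                {f"u{i}" for i in range(k)} | {f"u{20 + i}" for i in range(5 - k)},
                {"S": gene_set},
                universe,
            ).loc["S", "p_value"]
            for k in range(5)
        ]
        assert np.all(np.diff(p) < 0)

    def test_certain_overlap_has_p_one(self):
        u = {"a", "b", "c"}
        out = overlap_enrichment(u, {"S": u}, u)
        assert out.loc["S", "p_value"] == pytest.approx(1.0)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(set(), {"S": {"a"}}, set())
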