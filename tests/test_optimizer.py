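"""Hub-pool heuristics: screens, two search variants, and the fallback."""

import math

import networkx as nx
import pytest

from firsthit import (
    GraphSpec,
    combinatorial_search,
    coverage_rank,
    from_nx,
    generate,
    hub_fallback,
    objective_F,
    semi_greedy_search,
    top_hubs,
)
from firsthit.optimizer import (
    CandidateBudgetError,
    HeuristicParams,
    n_hub_subsets,
)

from conftest import exhaustive_min_F, random_connected_net


class TestTopHubs:
    def test_star_center_first(self, star6):
        assert top_hubs(star6, 1) == [0]

    def test_regular_graph_ties_by_label(self, k4):
        assert top_hubs(k4, 2) == [0, 1]

    def test_degree_sequence_order(self):
        # degrees: 0 and 1 high, 2 mid, 3 pendant
        g = nx.Graph(
            [(0, 1), (0, 2), (0, 4), (0, 5), (0, 6),
             (1, 2), (1, 4), (1, 5), (1, 6), (2, 3)]
        )
        net = from_nx(g)
        assert top_hubs(net, 3) == [0, 1, 2]

    def test_h_too_large_rejected(self, k4):
        with pytest.raises(ValueError):
            top_hubs(k4, 5)


class TestCoverageRank:
    def test_disjoint_pair_beats_adjacent_pair(self, barbell13):
        # one hub per clique covers both cliques; same-clique pairs overlap
        hubs = top_hubs(barbell13, 4)
        pairs = [tuple(sorted(p)) for p in
                 [(hubs[0], hubs[1]), (hubs[0], hubs[2])]]
        ranked = coverage_rank(barbell13, pairs, p=1, b=1)
        u, v = ranked[0]
        # winners live in different cliques (the bridge vertex is 6)
        assert (u < 6) != (v < 6) or 6 in (u, v)

    def test_radius_zero_ties_resolved_lexicographically(self, cycle6):
        pairs = [(2, 4), (0, 3), (1, 5)]
        ranked = coverage_rank(cycle6, pairs, p=0, b=3)
        assert ranked == [(0, 3), (1, 5), (2, 4)]

    def test_keep_all_when_b_large(self, cycle6):
        pairs = [(0, 1), (2, 3)]
        assert len(coverage_rank(cycle6, pairs, p=1, b=10)) == 2


class TestCombinatorialSearch:
    def test_star_k1_finds_center(self, star6):
        params = HeuristicParams(k=1, h=star6.n, b=6, q=6)
        r = combinatorial_search(star6, params, exact_final=True)
        assert r.A_hat.sorted() == (0,)

    def test_barbell_k2_spans_cliques(self, barbell13):
        params = HeuristicParams(k=2, h=barbell13.n, b=100, q=100)
        r = combinatorial_search(barbell13, params, exact_final=True)
        S, F_star = exhaustive_min_F(barbell13, 2)
        assert r.F_exact == pytest.approx(F_star)

    @pytest.mark.parametrize("seed", range(8))
    def test_full_parameters_reproduce_exhaustive_optimum(self, seed):
        net = random_connected_net(12, seed)
        k = 1 + seed % 3
        n_cand = math.comb(net.n, k)
        params = HeuristicParams(k=k, h=net.n, b=n_cand, q=n_cand)
        r = combinatorial_search(net, params, exact_final=True)
        _, F_star = exhaustive_min_F(net, k)
        assert r.F_exact == pytest.approx(F_star)

    def test_budget_error_directs_to_semi_greedy(self):
        net = random_connected_net(40, 0)
        params = HeuristicParams(k=5, h=40, b=5, q=5)
        with pytest.raises(CandidateBudgetError, match="semi_greedy"):
            combinatorial_search(net, params, candidate_budget=1000)

    def test_stage_log_sizes(self, barbell13):
        params = HeuristicParams(k=2, h=6, b=5, q=3, M1=50, M2=100)
        r = combinatorial_search(barbell13, params, seed=0)
        sizes = {rec.name: rec.size for rec in r.stage_log}
        assert sizes["hub_subsets"] == n_hub_subsets(6, 2)
        assert sizes["coverage"] == 5
        assert sizes["farness"] == 3
        assert sizes["mc_refine"] == 1
        assert r.A_hat.k == 2

    def test_deterministic_given_seed(self, barbell13):
        params = HeuristicParams(k=2, h=8, b=5, q=4, M1=50, M2=100)
        r1 = combinatorial_search(barbell13, params, seed=5)
        r2 = combinatorial_search(barbell13, params, seed=5)
        assert r1.A_hat == r2.A_hat
        assert r1.F_estimate.F_M == r2.F_estimate.F_M

    @pytest.mark.parametrize("seed", range(5))
    def test_enlarging_pool_never_hurts_exact_config(self, seed):
        net = random_connected_net(14, seed)
        values = []
        for h in (4, 8, net.n):
            n_cand = math.comb(h, 2)
            params = HeuristicParams(k=2, h=h, b=n_cand, q=n_cand)
            r = combinatorial_search(net, params, exact_final=True)
            values.append(r.F_exact)
        assert values[0] >= values[1] - 1e-9 >= values[2] - 2e-9


class TestSemiGreedy:
    def test_k2_result_is_the_seed_pair(self, barbell13):
        params = HeuristicParams(k=2, h=barbell13.n)
        r = semi_greedy_search(barbell13, params, exact_final=True)
        seeds = [rec for rec in r.stage_log if rec.name == "seed_pair"]
        assert seeds and seeds[0].kept[0] == r.A_hat.sorted()

    def test_barbell_one_hub_per_clique(self, barbell13):
        params = HeuristicParams(k=2, h=barbell13.n)
        r = semi_greedy_search(barbell13, params, exact_final=True)
        u, v = r.A_hat.sorted()
        assert (u < 6 and v > 6) or 6 in (u, v)

    def test_k1_best_single_hub_by_coverage(self, star6):
        r = semi_greedy_search(star6, HeuristicParams(k=1, h=4), exact_final=True)
        assert r.A_hat.sorted() == (0,)

    def test_remote_vertex_preferred_for_coverage_growth(self):
        # a star with a long pendant chain: after the center, the chain hub
        # adds more new coverage than any second leaf
        g = nx.star_graph(6)  # center 0, leaves 1..6
        g.add_edges_from([(6, 7), (7, 8), (8, 9), (9, 10), (7, 11), (8, 12)])
        net = from_nx(g)
        params = HeuristicParams(k=2, h=net.n, p=2)
        r = semi_greedy_search(net, params, exact_final=True)
        assert 0 in r.A_hat
        other = next(v for v in r.A_hat if v != 0)
        assert other >= 6  # deep in the chain, not a plain leaf

    def test_reports_farness_and_estimate(self, barbell13):
        params = HeuristicParams(k=3, h=8, M1=50, M2=100)
        r = semi_greedy_search(barbell13, params, seed=2)
        assert r.C_value >= 0
        assert r.F_estimate is not None
        assert r.F_estimate.F_M >= r.C_value  # conservative screen


class TestHubFallback:
    def test_unchanged_when_heuristic_wins(self, barbell13):
        params = HeuristicParams(k=2, h=barbell13.n, b=100, q=100)
        r = combinatorial_search(barbell13, params, exact_final=True)
        assert hub_fallback(barbell13, 2, r) is r

    def test_hub_set_wins_on_dense_core(self):
        # dense core whose two top hubs beat the greedy coverage pick
        g = nx.complete_graph(8)
        g.add_edges_from([(0, 8), (8, 9), (1, 10), (10, 11)])
        net = from_nx(g)
        params = HeuristicParams(k=2, h=net.n, p=2)
        r = semi_greedy_search(net, params, exact_final=True)
        fixed = hub_fallback(net, 2, r)
        hub_F = objective_F(net, tuple(top_hubs(net, 2)))
        assert fixed.best_F == pytest.approx(min(r.F_exact, hub_F))

    def test_never_worse_than_either_branch(self):
        for seed in range(5):
            net = random_connected_net(15, seed)
            params = HeuristicParams(k=2, h=6)
            r = semi_greedy_search(net, params, exact_final=True)
            fixed = hub_fallback(net, 2, r)
            hub_F = objective_F(net, tuple(top_hubs(net, 2)))
            assert fixed.best_F <= r.F_exact + 1e-9
            assert fixed.best_F <= hub_F + 1e-9


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            HeuristicParams(k=0)
        with pytest.raises(ValueError):
            HeuristicParams(k=2, q=6, b=5)
        with pytest.raises(ValueError):
            HeuristicParams(k=2, M1=100, M2=50)

    def test_default_pool_is_ten_k_capped_at_n(self, star6):
        assert HeuristicParams(k=1).pool_size(star6) == 6
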