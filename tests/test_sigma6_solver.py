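"""Sigma-6 solver: pruning, triplets, component classification, straight
bubble solutions, intersection graphs and oracle agreement."""

import itertools
from fractions import Fraction

import pytest

import sigmak as sk
from sigmak import sigma6_solver as s6
from sigmak.sigma4_solver import solve_sigma4

from helpers import (
    WGD_D,
    WGD_S,
    TRIPLET_D_SATURATED,
    TRIPLET_D_UNSATURATED,
    TRIPLET_S,
    genome,
    random_pair,
)

# an instance whose only ambiguous component is two 6-cycles sharing a
# D-S-D path (found by seeded search, frozen here)
DSD_S = "(-1) (-3 -4 -2)"
DSD_D = "(-1 4 3 -2 -2 -4 1 3)"


def pruned(s_text, d_text):
    abg = sk.build_abg(genome(s_text), genome(d_text))
    sk.fix_common(abg)
    sk.fix_symmetric_squares(abg)
    return abg, s6.prune(abg)


def brute_force_mis(ig):
    """Reference maximum-weight independent set by subset enumeration."""
    n = len(ig.players)
    best = Fraction(0)
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            cs = set(combo)
            if any(frozenset((i, j)) in ig.edges
                   for i, j in itertools.combinations(combo, 2)):
                continue
            best = max(best, sum((ig.players[i].weight for i in cs), Fraction(0)))
    return best


class TestPrune:
    def test_reference_instance(self):
        abg, pg = pruned(WGD_S, WGD_D)
        # square 1 carries the 2-cycle (fixed); square 2 resolves to a single
        # preserved pair during pruning
        assert pg.square_class == {1: "fixed", 2: "d"}
        C, P, M = s6.classify_components(pg)
        assert len(C) == 1 and len(P) == 4 and not M
        assert len(C) + Fraction(len(P), 2) == 3

    def test_pair_without_players_prunes_to_nothing(self):
        abg, pg = pruned("[1 2 3 4 5]", "(1 3 5 2 4) (1 3 5 2 4)")
        assert not pg.present_s and not pg.present_d and not pg.zero_paths
        assert sk.oracle_best(sk.build_abg(
            genome("[1 2 3 4 5]"), genome("(1 3 5 2 4) (1 3 5 2 4)")), 6)[0] == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_prune_preserves_the_sigma6_score(self, seed):
        s, d = random_pair(seed)
        fresh = sk.oracle_best(sk.build_abg(s, d), 6)[0]
        abg = sk.build_abg(s, d)
        sk.fix_common(abg)
        sk.fix_symmetric_squares(abg)
        s6.prune(abg)  # fixes resolved/pruned squares as a side effect
        assert sk.oracle_best(abg, 6)[0] == fresh


class TestTriplets:
    def test_saturated_triplet_scores_two(self):
        abg, pg = pruned(TRIPLET_S, TRIPLET_D_SATURATED)
        trips = s6.detect_triplets(pg)
        assert [(t.saturated, t.score) for t in trips] == [(True, 2)]

    def test_unsaturated_triplet_scores_one(self):
        abg, pg = pruned(TRIPLET_S, TRIPLET_D_UNSATURATED)
        trips = s6.detect_triplets(pg)
        assert [(t.saturated, t.score) for t in trips] == [(False, 1)]

    def test_three_squares_with_too_many_pruned_vertices_is_no_triplet(self):
        s_text, d_text = TRIPLET_S, "(1) (2) (2) (3) [1] [3]"
        abg, pg = pruned(s_text, d_text)
        assert not s6.detect_triplets(pg)
        res = s6.solve_sigma6(sk.build_abg(genome(s_text), genome(d_text)))
        oracle = sk.oracle_best(sk.build_abg(genome(s_text), genome(d_text)), 6)[0]
        assert res.score == oracle

    def test_triplet_solver_agrees_with_oracle(self):
        for d_text in (TRIPLET_D_SATURATED, TRIPLET_D_UNSATURATED):
            s, d = genome(TRIPLET_S), genome(d_text)
            res = s6.solve_sigma6(sk.build_abg(s, d))
            assert res.score == sk.oracle_best(sk.build_abg(s, d), 6)[0]


class TestStraightSolution:
    def test_two_intersecting_six_cycles(self):
        abg, pg = pruned(DSD_S, DSD_D)
        M = [c for c in pg.components if c.ambiguous_squares]
        assert len(M) == 1
        comp = M[0]
        cycles = [p for p in comp.players if p.kind == "cycle"]
        assert len(comp.players) == 2 and len(cycles) == 2
        sol = s6.straight_bubble_solution(pg, comp)
        best_local = s6._enumerate_component(pg, comp)[0]
        assert sol.best_score == best_local == 1

    def test_rejects_components_with_paths(self):
        abg, pg = pruned(WGD_S, WGD_D)
        # synthesize: any resolved path component must be refused
        comp = next(c for c in pg.components
                    if any(p.kind == "path" for p in c.players))
        with pytest.raises(ValueError):
            s6.straight_bubble_solution(pg, comp)

    @pytest.mark.parametrize("seed", [3, 9, 21, 33, 45, 57, 69, 81])
    def test_straight_solution_matches_local_enumeration(self, seed):
        s, d = random_pair(seed * 3)  # mode 0: circular-only
        abg = sk.build_abg(s, d)
        sk.fix_common(abg)
        sk.fix_symmetric_squares(abg)
        pg = s6.prune(abg)
        for comp in pg.components:
            if not comp.ambiguous_squares or s6._is_triplet(pg, comp):
                continue
            if any(p.kind == "path" for p in comp.players):
                continue
            try:
                sol = s6.straight_bubble_solution(pg, comp)
            except s6._Surprise:
                continue
            assert sol.best_score == s6._enumerate_component(pg, comp)[0]


class TestIntersectionGraph:
    def test_two_six_cycles_sharing_a_dsd_path(self):
        abg, pg = pruned(DSD_S, DSD_D)
        comp = next(c for c in pg.components if c.ambiguous_squares)
        ig = s6.build_intersection_graph(comp)
        assert len(ig.players) == 2 and len(ig.edges) == 1

    def test_lone_two_path_is_an_isolated_half_weight_vertex(self):
        abg, pg = pruned(WGD_S, WGD_D)
        comp = next(
            c for c in pg.components
            if len(c.players) == 1 and c.players[0].kind == "path"
            and c.players[0].length == 2
        )
        ig = s6.build_intersection_graph(comp)
        assert len(ig.players) == 1 and not ig.edges
        assert ig.players[0].weight == Fraction(1, 2)

    @pytest.mark.parametrize("seed", range(0, 60, 2))
    def test_mis_of_intersection_graph_equals_component_score(self, seed):
        s, d = random_pair(seed)
        abg = sk.build_abg(s, d)
        sk.fix_common(abg)
        sk.fix_symmetric_squares(abg)
        pg = s6.prune(abg)
        for comp in pg.components:
            if not comp.ambiguous_squares or len(comp.players) > 14:
                continue
            forced = [
                p for p in comp.players
                if all(abg.square(si).fixed is not None for si, _ in p.s_edges)
            ]
            if forced:
                continue
            ig = s6.build_intersection_graph(comp)
            assert brute_force_mis(ig) == s6._enumerate_component(pg, comp)[0]


class TestAlternatingSelections:
    """The path-line / double-line selection rules against a brute-force
    maximum-weight independent set on the same shapes."""

    def mwis(self, n, edges, w):
        nodes = list(range(n))
        weight = {i: w for i in nodes}
        total, sel = s6._mwis_exact(nodes, {frozenset(e) for e in edges}, weight)
        assert all(frozenset((i, j)) not in {frozenset(e) for e in edges}
                   for i in sel for j in sel if i != j)
        return total

    def test_isolated_double_line_of_length_four(self):
        # ladder: two parallel 4-vertex lines + rungs; 4-path weights 1/2
        edges = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)] + [
            (i, i + 4) for i in range(4)
        ]
        assert self.mwis(8, edges, Fraction(1, 2)) == 2

    def test_unsaturated_path_line_of_length_five(self):
        edges = [(i, i + 1) for i in range(4)]
        assert self.mwis(5, edges, Fraction(1, 2)) == Fraction(3, 2)

    def test_cyclic_path_line_of_length_five(self):
        edges = [(i, (i + 1) % 5) for i in range(5)]
        assert self.mwis(5, edges, Fraction(1, 2)) == 1


class TestSolveSigma6:
    def test_reference_instance(self):
        res = s6.solve_sigma6(sk.build_abg(genome(WGD_S), genome(WGD_D)))
        assert res.score == 3 and res.distance == 3

    def test_doubling_scores_the_maximum(self):
        s = genome("(1 2 3) [4 5]")
        for b in sk.enumerate_doublings(s):
            res = s6.solve_sigma6(sk.build_abg(s, b))
            assert res.distance == 0

    @pytest.mark.parametrize("seed", range(150))
    def test_oracle_agreement(self, seed):
        s, d = random_pair(seed)
        abg = sk.build_abg(s, d)
        res = s6.solve_sigma6(abg)
        oracle = sk.oracle_best(sk.build_abg(s, d), 6)[0]
        assert res.score == oracle
        assert sk.k_score(abg, res.solution, 6) == res.score

    @pytest.mark.parametrize("seed", range(0, 90, 3))
    def test_structural_and_enumeration_routes_agree(self, seed):
        # enum_bound=0 forces the structural path (with the exact MWIS
        # fallback) even on small components
        s, d = random_pair(seed)
        a = s6.solve_sigma6(sk.build_abg(s, d)).score
        b = s6.solve_sigma6(sk.build_abg(s, d), enum_bound=0).score
        assert a == b

    @pytest.mark.parametrize("seed", range(30))
    def test_score_hierarchy_across_k(self, seed):
        s, d = random_pair(seed)
        s2 = 2 * len(s.families()) - sk.double_distance_sigma2(s, d)
        s4 = solve_sigma4(sk.build_abg(s, d)).score
        score6 = s6.solve_sigma6(sk.build_abg(s, d)).score
        assert s2 <= s4 <= score6

    def test_operation_count_scales_linearly(self):
        ops = {}
        for n in (1000, 2000):
            cfg = sk.GeneratorConfig(n, 2, 2, n // 10, seed=11)
            s, d = sk.random_instance(cfg)
            ops[n] = s6.solve_sigma6(sk.build_abg(s, d)).operations
        assert ops[2000] <= 3 * ops[1000]


def test_dot_exports_are_well_formed():
    abg, pg = pruned(DSD_S, DSD_D)
    dot = s6.pruned_to_dot(pg)
    assert dot.startswith("graph") and "--" in dot
    comp = next(c for c in pg.components if c.ambiguous_squares)
    dot2 = s6.intersection_to_dot(s6.build_intersection_graph(comp))
    assert "cycle" in dot2
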