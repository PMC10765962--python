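"""Ambiguous breakpoint graph, solutions, k-scores, the exhaustive oracle and
the closed-form sigma-2 double distance."""

from collections import Counter
from fractions import Fraction

import pytest

import sigmak as sk
from sigmak.ambiguous_graph import OracleBoundError
from sigmak.genomes import Extremity, GenomeFormatError, swap_copies, singularize

from helpers import WGD_D, WGD_S, genome, random_pair


@pytest.fixture
def fig3():
    return sk.build_abg(genome(WGD_S), genome(WGD_D))


def ext(fam, side, copy):
    return Extremity(fam, side, copy)


class TestConstruction:
    def test_reference_instance_shape(self, fig3):
        assert fig3.a_star == 2 and fig3.n_star == 3
        assert len(fig3.d_edges) == 4
        assert fig3.s_telomeres == {
            ext("1", "t", "a"), ext("1", "t", "b"),
            ext("3", "h", "a"), ext("3", "h", "b"),
        }
        assert fig3.d_telomeres == {
            ext("1", "t", "a"), ext("1", "h", "b"),
            ext("3", "h", "b"), ext("2", "h", "b"),
        }

    def test_square_count_is_families_minus_linear_chromosomes(self, fig3):
        assert fig3.a_star == fig3.n_star - fig3.s.n_linear()

    def test_degenerate_single_gene_instance(self):
        abg = sk.build_abg(genome("[1]"), genome("[1] [1]"))
        assert abg.a_star == 0 and not abg.d_edges
        assert len(abg.vertices) == 4

    def test_family_mismatch_rejected(self):
        with pytest.raises(GenomeFormatError, match="symmetric difference"):
            sk.build_abg(genome("[1 2]"), genome("[1 3] [1 3]"))


class TestSolutions:
    def test_stated_solution_census(self, fig3):
        cs = sk.decompose(sk.induce(fig3, (sk.PARALLEL, sk.CROSSED)))
        assert cs.c == Counter({2: 1})
        assert cs.p == Counter({0: 2, 2: 1, 4: 1})

    def test_all_parallel_census(self, fig3):
        cs = sk.decompose(sk.induce(fig3, (sk.PARALLEL, sk.PARALLEL)))
        assert cs.c == Counter({2: 1})
        assert cs.p == Counter({0: 2, 3: 2})

    def test_switch_flips_exactly_one_square(self, fig3):
        tau = (sk.PARALLEL, sk.CROSSED)
        assert sk.switch(tau, 1) == (sk.CROSSED, sk.CROSSED)
        assert sk.switch(sk.switch(tau, 2), 2) == tau
        complement = sk.switch(sk.switch(tau, 1), 2)
        assert complement == (sk.CROSSED, sk.PARALLEL)
        with pytest.raises(IndexError):
            sk.switch(tau, 3)

    def test_switch_changes_only_that_squares_edges(self, fig3):
        tau = (sk.PARALLEL, sk.PARALLEL)
        g1 = sk.induce(fig3, tau)
        g2 = sk.induce(fig3, sk.switch(tau, 2))
        diff = set(map(frozenset, g1.edges1)) ^ set(map(frozenset, g2.edges1))
        touched = {v for e in diff for v in e}
        assert touched <= set(fig3.squares[1].vertices)

    def test_k_scores_of_stated_solution(self, fig3):
        tau = (sk.PARALLEL, sk.CROSSED)
        assert sk.k_score(fig3, tau, 6) == 3
        assert sk.k_score(fig3, tau, 2) == 2

    @pytest.mark.parametrize("seed", range(15))
    def test_k_score_cumulative_in_k(self, seed):
        s, d = random_pair(seed)
        abg = sk.build_abg(s, d)
        tau = abg.default_solution()
        scores = [sk.k_score(abg, tau, k) for k in (2, 4, 6, sk.INF)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))


class TestOracle:
    def test_reference_scores(self, fig3):
        assert sk.oracle_best(fig3, 6)[0] == 3
        score2, _ = sk.oracle_best(fig3, 2)
        assert score2 == 2 and 2 * fig3.n_star - score2 == 4

    def test_doubling_reaches_the_maximum(self):
        s = genome("(1 2)")
        abg = sk.build_abg(s, genome("(1 2) (1 2)"))
        for k in (2, 4, 6, sk.INF):
            assert sk.oracle_best(abg, k)[0] == 2 * abg.n_star == 4

    def test_bound_refusal(self):
        s = sk.random_singular_genome(sk.GeneratorConfig(12, 1, 0, seed=3))
        d = sk.random_duplicated_from(s, sk.GeneratorConfig(12, 1, 0, 4, seed=3))
        abg = sk.build_abg(s, d)
        with pytest.raises(OracleBoundError):
            sk.oracle_best(abg, 6, cap=5)

    @pytest.mark.parametrize("seed", range(20))
    def test_score_non_decreasing_in_k(self, seed):
        s, d = random_pair(seed)
        abg = sk.build_abg(s, d)
        best = sk.oracle_best_scores(abg, [2, 4, 6, sk.INF])
        scores = [best[k][0] for k in (2, 4, 6, sk.INF)]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    @pytest.mark.parametrize("seed", range(12))
    def test_invariance_under_singularization_relabeling(self, seed):
        import random

        s, d = random_pair(seed)
        d_sing = singularize(d)
        fams = [f for f in sorted(s.families()) if random.Random(seed).random() < 0.5]
        relabeled = swap_copies(d_sing, set(fams))
        a1 = sk.build_abg(s, d_sing)
        a2 = sk.build_abg(s, relabeled)
        b1 = sk.oracle_best_scores(a1, [2, 4, 6])
        b2 = sk.oracle_best_scores(a2, [2, 4, 6])
        for k in (2, 4, 6):
            assert b1[k][0] == b2[k][0]


class TestDoubleDistance:
    def test_sigma2_closed_formula_reference(self):
        assert sk.double_distance_sigma2(genome(WGD_S), genome(WGD_D)) == 4

    def test_sigma2_zero_against_any_doubling(self):
        s = genome("(1 2) [3 4]")
        for b in sk.enumerate_doublings(s):
            assert sk.double_distance_sigma2(s, b) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_sigma2_formula_matches_oracle(self, seed):
        s, d = random_pair(seed)
        abg = sk.build_abg(s, d)
        score, _ = sk.oracle_best(abg, 2)
        assert sk.double_distance_sigma2(s, d) == 2 * abg.n_star - score

    @pytest.mark.parametrize(
        "k,expected", [(6, 3), (4, Fraction(7, 2)), (2, 4)]
    )
    def test_dispatch_on_reference_instance(self, k, expected):
        res = sk.double_distance(genome(WGD_S), genome(WGD_D), k)
        assert res.distance == expected
        # the returned solution re-scores to the reported value
        abg = sk.build_abg(genome(WGD_S), genome(WGD_D))
        assert 2 * abg.n_star - sk.k_score(abg, res.solution, k) == expected

    def test_unsupported_k_requires_oracle(self):
        s, d = genome(WGD_S), genome(WGD_D)
        with pytest.raises(ValueError, match="oracle"):
            sk.double_distance(s, d, 8)
        assert sk.double_distance(s, d, 8, method="oracle").distance == 3
        assert sk.double_distance(s, d, sk.INF, method="oracle").distance == 3
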