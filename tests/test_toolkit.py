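"""Instance generator, DCJ surgery, rational formatting and the CLI."""

import random
from fractions import Fraction
import pytest
from click.testing import CliRunner

import sigmak as sk
from sigmak.cli import main
from sigmak.genomes import Extremity, adjacency_multiset, telomere_multiset
from sigmak.toolkit import _rebuild_genome, apply_random_dcjs, format_rational

from helpers import PAIR_A, PAIR_B, WGD_D, WGD_S, genome


class TestGenerator:
    def test_reproducibility(self):
        cfg = sk.GeneratorConfig(8, 1, 2, 5, seed=42)
        s1, d1 = sk.random_instance(cfg)
        s2, d2 = sk.random_instance(cfg)
        assert s1.format() == s2.format()
        assert d1.format() == d2.format()

    def test_requested_shape(self):
        cfg = sk.GeneratorConfig(6, 1, 2, seed=0)
        s = sk.random_singular_genome(cfg)
        assert sk.classify_genome(s) == "singular"
        assert s.n_linear() == 1 and s.n_circular() == 2
        n_adj = sum(adjacency_multiset(s).values())
        n_tel = sum(telomere_multiset(s).values())
        assert n_adj + n_tel / 2 == 6

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            sk.GeneratorConfig(2, 2, 1)
        with pytest.raises(ValueError):
            sk.GeneratorConfig(5, 0, 0)

    def test_zero_dcjs_gives_an_exact_doubling(self):
        cfg = sk.GeneratorConfig(6, 1, 1, n_dcj=0, seed=9)
        s, d = sk.random_instance(cfg)
        assert d in list(sk.enumerate_doublings(s))
        for k in (2, 4, 6):
            assert sk.double_distance(s, d, k).distance == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_dcj_count_bounds_the_double_distance(self, seed):
        rng = random.Random(seed)
        n_dcj = rng.randint(0, 4)
        cfg = sk.GeneratorConfig(rng.randint(4, 6), 1, 1, n_dcj, seed=seed)
        s, d = sk.random_instance(cfg)
        abg = sk.build_abg(s, d)
        score, _ = sk.oracle_best(abg, sk.INF)
        assert 2 * abg.n_star - score <= n_dcj

    @pytest.mark.parametrize("seed", range(10))
    def test_generated_pairs_build_valid_abgs(self, seed):
        cfg = sk.GeneratorConfig(7, 1, 1, 4, seed=seed)
        s, d = sk.random_instance(cfg)
        abg = sk.build_abg(s, d)
        assert abg.a_star == len(s.families()) - s.n_linear()


class TestDcjSurgery:
    def test_crosswise_rejoin_is_an_inversion(self):
        # cut [1 2 3 4] between 1|2 and 3|4, rejoin crosswise -> [1 -3 -2 4]
        g = genome("[1 2 3 4]")
        adjacencies = set(adjacency_multiset(g))
        telomeres = set(telomere_multiset(g))
        h = lambda f: Extremity(f, "h")
        t = lambda f: Extremity(f, "t")
        adjacencies -= {frozenset((h("1"), t("2"))), frozenset((h("3"), t("4")))}
        adjacencies |= {frozenset((h("1"), h("3"))), frozenset((t("2"), t("4")))}
        rebuilt = _rebuild_genome(adjacencies, telomeres)
        assert rebuilt == genome("[1 -3 -2 4]")

    @pytest.mark.parametrize("seed", range(8))
    def test_random_dcjs_preserve_gene_content(self, seed):
        s = sk.random_singular_genome(sk.GeneratorConfig(8, 2, 1, seed=seed))
        doubled = sk.genomes.labeled_doubling(s, [False])
        evolved = apply_random_dcjs(doubled, 5, random.Random(seed))
        assert sorted(g.family_key for g in evolved.genes) == sorted(
            g.family_key for g in doubled.genes
        )


class TestFormatRational:
    @pytest.mark.parametrize(
        "value,expected",
        [(Fraction(5, 2), "2.5"), (Fraction(3), "3"), (Fraction(0), "0"),
         (Fraction(7, 2), "3.5")],
    )
    def test_half_integers_print_exactly(self, value, expected):
        assert format_rational(value) == expected


class TestCli:
    @pytest.fixture
    def runner(self):
        return CliRunner()

    def write(self, tmp_path, name, text):
        p = tmp_path / name
        p.write_text(text + "\n")
        return str(p)

    def test_distance_breakpoint_and_dcj(self, runner, tmp_path):
        a = self.write(tmp_path, "a.txt", PAIR_A)
        b = self.write(tmp_path, "b.txt", PAIR_B)
        out = runner.invoke(main, ["distance", "--k", "2", a, b])
        assert out.exit_code == 0 and out.output.strip() == "2.5"
        out = runner.invoke(main, ["distance", "--k", "inf", a, b])
        assert out.exit_code == 0 and out.output.strip() == "2"

    def test_cli_output_parses_back_exactly(self, runner, tmp_path):
        a = self.write(tmp_path, "a.txt", PAIR_A)
        b = self.write(tmp_path, "b.txt", PAIR_B)
        out = runner.invoke(main, ["distance", "--k", "2", a, b])
        assert Fraction(out.output.strip()) == sk.sigma_distance(
            genome(PAIR_A), genome(PAIR_B), 2
        )

    def test_double_distance_sigma6(self, runner, tmp_path):
        s = self.write(tmp_path, "s.txt", WGD_S)
        d = self.write(tmp_path, "d.txt", WGD_D)
        out = runner.invoke(main, ["double-distance", "--k", "6", s, d])
        assert out.exit_code == 0 and out.output.strip() == "3"
        out = runner.invoke(main, ["double-distance", "--k", "6", "--oracle", s, d])
        assert out.exit_code == 0 and out.output.strip() == "3"

    def test_validation_failure_exits_nonzero(self, runner, tmp_path):
        s = self.write(tmp_path, "s.txt", "[1 2]")
        d = self.write(tmp_path, "d.txt", "[1 3] [1 3]")
        out = runner.invoke(main, ["double-distance", "--k", "6", s, d])
        assert out.exit_code != 0
        bad = self.write(tmp_path, "bad.txt", "[1 2")
        out = runner.invoke(main, ["distance", bad, s])
        assert out.exit_code != 0

    def test_generate_is_reproducible_and_valid(self, runner, tmp_path):
        args = ["generate", "--families", "8", "--linear", "1", "--circular", "1",
                "--dcj", "3", "--seed", "5",
                "--out-singular", str(tmp_path / "S.txt"),
                "--out-duplicated", str(tmp_path / "D.txt")]
        assert runner.invoke(main, args).exit_code == 0
        first = (tmp_path / "S.txt").read_text(), (tmp_path / "D.txt").read_text()
        assert runner.invoke(main, args).exit_code == 0
        second = (tmp_path / "S.txt").read_text(), (tmp_path / "D.txt").read_text()
        assert first == second
        s = genome(first[0])
        d = genome(first[1])
        sk.build_abg(s, d)  # validates

    def test_generate_with_yaml_config(self, runner, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("families: 6\nseed: 3\ncircular: 1\n")
        args = ["generate", "--config", str(cfg),
                "--out-singular", str(tmp_path / "S.txt"),
                "--out-duplicated", str(tmp_path / "D.txt")]
        assert runner.invoke(main, args).exit_code == 0
        assert len(genome((tmp_path / "S.txt").read_text()).families()) == 6

    @pytest.mark.parametrize("which", ["bg", "abg", "pruned", "intersection"])
    def test_graph_exports(self, runner, tmp_path, which):
        if which == "bg":
            a = self.write(tmp_path, "a.txt", PAIR_A)
            b = self.write(tmp_path, "b.txt", PAIR_B)
        else:
            a = self.write(tmp_path, "a.txt", WGD_S)
            b = self.write(tmp_path, "b.txt", WGD_D)
        out_file = tmp_path / f"{which}.dot"
        out = runner.invoke(
            main, ["graph", "--which", which, "--dot", str(out_file), a, b]
        )
        assert out.exit_code == 0, out.output
        assert out_file.read_text().startswith("graph")
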