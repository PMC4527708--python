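"""Grammatical evolution: mapping oracle, operators, evolutionary loop."""

import numpy as np
import pytest

from swarmforage import make_arena
from swarmforage.evolve import (
    CONTROLLER_GRAMMAR,
    EvolutionConfig,
    Grammar,
    crossover,
    derive,
    evaluate_genotype,
    evolve,
    map_genotype,
    mutate,
    random_genotype,
    select_parent,
)

TOY = Grammar({"S": [("a", "S"), ("b",)]}, "S")


class TestDerivation:
    def test_toy_grammar_hand_traced(self):
        # S --codon 1--> b
        assert derive(TOY, [1]) == ["b"]
        # S --0--> aS --1--> ab
        assert derive(TOY, [0, 1]) == ["a", "b"]
        # S -0-> aS -0-> aaS -0-> aaaS -1-> aaab
        assert derive(TOY, [0, 0, 0, 1]) == ["a", "a", "a", "b"]

    def test_wrapping_reuses_codons(self):
        # [0, 0]: a a (wrap) a a (wrap) ... exhausts max_wraps -> invalid
        assert derive(TOY, [0, 0], max_wraps=3) is None
        # [0, 1] needs no wrap; [2, 1]: 2 % 2 = 0 -> a, then b
        assert derive(TOY, [2, 1]) == ["a", "b"]

    def test_single_alternative_consumes_no_codon(self):
        g = Grammar({"S": [("X", "X")], "X": [("x",), ("y",)]}, "S")
        # only <X> consumes codons; two expansions, two codons
        assert derive(g, [0, 1]) == ["x", "y"]

    def test_purity(self):
        geno = [7, 3, 9, 200, 41]
        assert derive(TOY, geno) == derive(TOY, list(geno))
        g = random_genotype(np.random.default_rng(4))
        rs1 = map_genotype(g)
        rs2 = map_genotype(list(g))
        assert rs1.rules == rs2.rules
        assert rs1.initial_behavior == rs2.initial_behavior

    def test_locality_beyond_consumed_prefix(self):
        """Codons after the derivation's consumed prefix are silent."""
        rng = np.random.default_rng(3)
        geno = random_genotype(rng)
        rs = map_genotype(geno)
        assert rs is not None
        tokens = derive(CONTROLLER_GRAMMAR, geno)
        # count codons actually consumed by re-deriving with a truncation
        # search: find the shortest prefix giving the same tokens
        lo, hi = 1, len(geno)
        while lo < hi:
            mid = (lo + hi) // 2
            if derive(CONTROLLER_GRAMMAR, geno[:mid]) == tokens:
                hi = mid
            else:
                lo = mid + 1
        consumed = lo
        if consumed < len(geno):
            tail_changed = list(geno)
            tail_changed[-1] = (tail_changed[-1] + 123) % 256
            assert map_genotype(tail_changed).rules == rs.rules

    def test_unreachable_nonterminal_rejected(self):
        with pytest.raises(ValueError):
            Grammar({"S": [("a",)], "T": [("b",)]}, "S")

    def test_empty_genotype_invalid(self):
        assert derive(TOY, []) is None

    def test_controller_genotypes_map_to_valid_rulesets(self):
        from swarmforage.rules import validate_ruleset

        rng = np.random.default_rng(0)
        n_valid = 0
        for _ in range(100):
            rs = map_genotype(random_genotype(rng))
            if rs is None:
                continue
            n_valid += 1
            assert validate_ruleset(rs) == []
            assert rs.n_rules >= 1
        assert n_valid > 60


class TestOperators:
    def test_identical_parents_give_identical_children(self, rng):
        p = [1, 2, 3, 4, 5]
        c1, c2 = crossover(p, p, rng, probability=1.0)
        assert sorted(len(c) for c in (c1, c2)) == sorted([len(c1), len(c2)])
        assert set(c1) <= set(p) and set(c2) <= set(p)

    def test_forced_cut_exchanges_tails(self):
        class FixedRng:
            def random(self):
                return 0.0  # always cross over

            def integers(self, lo, hi):
                return 2

        c1, c2 = crossover([1, 1, 1, 1], [9, 9, 9], FixedRng(), probability=0.3)
        assert c1 == [1, 1, 9]
        assert c2 == [9, 9, 1, 1]

    def test_crossover_rate_monte_carlo(self, rng):
        """Non-copy events occur at the configured 0.3 rate."""
        p1 = list(range(50))
        p2 = list(range(100, 160))
        n = 10_000
        crossed = 0
        for _ in range(n):
            c1, _ = crossover(p1, p2, rng, probability=0.3)
            if c1 != p1:
                crossed += 1
        assert crossed / n == pytest.approx(0.30, abs=0.015)

    def test_mutation_probability_zero_is_identity(self, rng):
        g = list(range(100))
        assert mutate(g, rng, probability=0.0) == g

    def test_mutation_probability_one_resamples_everything(self, rng):
        g = [300] * 50  # sentinel outside codon range
        m = mutate(g, rng, probability=1.0)
        assert all(0 <= c <= 255 for c in m)

    def test_mutation_rate_monte_carlo(self, rng):
        """~5 codons mutate per 100-codon genotype at p=0.05."""
        g = [999] * 100
        total = 0
        n = 10_000
        for _ in range(n):
            total += sum(1 for c in mutate(g, rng, probability=0.05) if c != 999)
        assert total / n == pytest.approx(5.0, abs=0.5)

    def test_selection_uniform_fitness(self, rng):
        pop = list(range(4))
        counts = np.zeros(4)
        for _ in range(8000):
            counts[select_parent(pop, [1, 1, 1, 1], rng)] += 1
        assert counts / 8000 == pytest.approx([0.25] * 4, abs=0.02)

    def test_selection_all_mass_on_single_positive(self, rng):
        pop = ["a", "b", "c"]
        for _ in range(50):
            assert select_parent(pop, [0, 0, 3], rng) == "c"

    def test_selection_ratio_monte_carlo(self, rng):
        pop = ["a", "b"]
        hits = sum(select_parent(pop, [1, 3], rng) == "b" for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.75, abs=0.015)

    def test_selection_zero_sum_uniform_fallback(self, rng):
        counts = np.zeros(3)
        for _ in range(6000):
            counts[select_parent([0, 1, 2], [0, 0, 0], rng)] += 1
        assert counts / 6000 == pytest.approx([1 / 3] * 3, abs=0.03)

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            select_parent([0, 1], [1, -1], rng)


class TestEvaluateGenotype:
    def test_invalid_genotype_scores_zero(self, sloped_arena):
        assert evaluate_genotype([0], sloped_arena, T=100) == 0.0

    def test_deterministic(self, sloped_arena):
        rng = np.random.default_rng(5)
        g = random_genotype(rng)
        a = evaluate_genotype(g, sloped_arena, evaluations=2, T=300, seed=9)
        b = evaluate_genotype(g, sloped_arena, evaluations=2, T=300, seed=9)
        assert a == b


@pytest.fixture(scope="module")
def tiny_history():
    cfg = EvolutionConfig(
        population_size=8, generations=6, evaluations=1, T=200.0, seed=3,
        min_init_len=20, max_init_len=60,
    )
    return evolve(cfg, make_arena("sloped"))


class TestEvolve:

    def test_history_shape(self, tiny_history):
        df = tiny_history.df
        assert len(df) == 6
        assert list(df.generation) == list(range(6))

    def test_best_ever_monotone(self, tiny_history):
        be = tiny_history.df.best_ever_fitness.values
        assert (np.diff(be) >= 0).all()

    def test_full_elitism_freezes_population(self):
        cfg = EvolutionConfig(
            population_size=6, generations=3, evaluations=1, T=150.0, seed=1,
            elitism=1.0,
        )
        h = evolve(cfg, make_arena("sloped"))
        # with elitism 1.0 the genotype pool is constant after generation 0
        assert h.genotypes[1] == h.genotypes[2]

    def test_reproducible_run(self):
        cfg = EvolutionConfig(population_size=6, generations=3, evaluations=1,
                              T=150.0, seed=11)
        h1 = evolve(cfg, make_arena("sloped"))
        h2 = evolve(cfg, make_arena("sloped"))
        assert h1.df.equals(h2.df)
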