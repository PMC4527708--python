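"""Grammatical evolution of rule-based foraging controllers.

A genotype is a variable-length string of 8-bit integer codons.  The
phenotype is obtained by a standard grammatical-evolution derivation:
starting from the grammar's axiom, the leftmost nonterminal is expanded
by the production alternative indexed by ``codon mod n_alternatives``
(nonterminals with a single alternative consume no codon); the codon
stream wraps around up to ``max_wraps`` times, and a derivation still
incomplete after that maps to an *invalid* phenotype with fitness 0.

The controller grammar spans exactly the rule formalism of
:mod:`swarmforage.rules`: a rule set is one or more rules, each with one
or more preconditions over the eight state variables, a non-empty
subset of the three low-level behaviors, and one or more probabilistic
actions (behavior switch, pickup, drop, or a state-variable write) with
probabilities drawn from a 20-value log-spaced grid on [0.001, 1].

Selection follows group performance only: homogeneous teams, fitness =
items delivered in a seeded episode, averaged over independent
evaluations; roulette-wheel selection, single-point crossover with
probability 0.3, per-codon uniform mutation with probability 0.05 and
generational replacement with 5% elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import mean_linear_speed, specialization_degree
from .rules import Rule, RuleSet, validate_ruleset
from .sim import run_episode
from .world import ArenaConfig

__all__ = [
    "Grammar",
    "CONTROLLER_GRAMMAR",
    "EvolutionConfig",
    "EvolutionHistory",
    "derive",
    "map_genotype",
    "random_genotype",
    "crossover",
    "mutate",
    "select_parent",
    "evaluate_genotype",
    "evolve",
]

CODON_MAX = 255

#: action probabilities p_l are drawn from a log-spaced grid: rules are
#: scanned at 10 Hz, so meaningful event rates span ~0.01/s (drop after
#: seconds of carrying) to ~10/s (immediate), i.e. three decades
PROB_GRID = (
    0.001, 0.0018, 0.0032, 0.0056, 0.01, 0.018, 0.032, 0.056, 0.1, 0.15,
    0.22, 0.32, 0.42, 0.56, 0.68, 0.78, 0.87, 0.93, 0.97, 1.0,
)


@dataclass(frozen=True)
class Grammar:
    """Context-free grammar in expanded BNF form.

    ``productions`` maps each nonterminal to its list of alternatives;
    an alternative is a tuple of symbols, and a symbol is a nonterminal
    (a key of ``productions``) or a terminal token.
    """

    productions: dict
    start: str

    def __post_init__(self):
        if self.start not in self.productions:
            raise ValueError(f"start symbol {self.start!r} has no production")
        reachable = set()
        stack = [self.start]
        while stack:
            nt = stack.pop()
            if nt in reachable:
                continue
            reachable.add(nt)
            for alt in self.productions[nt]:
                for sym in alt:
                    if sym in self.productions and sym not in reachable:
                        stack.append(sym)
        unreachable = set(self.productions) - reachable
        if unreachable:
            raise ValueError(f"unreachable nonterminals: {sorted(unreachable)}")

    def is_nonterminal(self, sym: str) -> bool:
        return sym in self.productions


def derive(grammar: Grammar, codons, max_wraps: int = 3, max_expansions: int = 100_000):
    """Leftmost grammatical-evolution derivation.

    Returns the terminal token list, or ``None`` when the codon stream
    (wrapped at most ``max_wraps`` times) is exhausted before the
    derivation completes.  A pure function of its arguments.
    """
    codons = list(codons)
    if not codons:
        return None
    out = []
    stack = [grammar.start]
    idx = 0
    wraps = 0
    expansions = 0
    while stack:
        expansions += 1
        if expansions > max_expansions:
            return None
        sym = stack.pop()
        if not grammar.is_nonterminal(sym):
            out.append(sym)
            continue
        alts = grammar.productions[sym]
        if len(alts) == 1:
            choice = alts[0]
        else:
            if idx >= len(codons):
                wraps += 1
                if wraps > max_wraps:
                    return None
                idx = 0
            choice = alts[codons[idx] % len(alts)]
            idx += 1
        for s in reversed(choice):
            stack.append(s)
    return out


# ---------------------------------------------------------------------------
# the controller grammar
# ---------------------------------------------------------------------------

_VARS = ("in_nest", "in_cache", "in_slope", "in_source", "carrying", "want_pickup", "M1", "M2")
_BSETS = ("P", "A", "R", "PA", "PR", "AR", "PAR")
_BSET_MAP = {
    "P": frozenset({"PHOTOTAXIS"}),
    "A": frozenset({"ANTI_PHOTOTAXIS"}),
    "R": frozenset({"RANDOM_WALK"}),
    "PA": frozenset({"PHOTOTAXIS", "ANTI_PHOTOTAXIS"}),
    "PR": frozenset({"PHOTOTAXIS", "RANDOM_WALK"}),
    "AR": frozenset({"ANTI_PHOTOTAXIS", "RANDOM_WALK"}),
    "PAR": frozenset({"PHOTOTAXIS", "ANTI_PHOTOTAXIS", "RANDOM_WALK"}),
}

CONTROLLER_GRAMMAR = Grammar(
    productions={
        # the genotype encodes the whole controller, including the
        # behavior the robots boot into at t=0
        "<ruleset>": [("INIT", "<ibeh>", "<rules>")],
        "<ibeh>": [("PHOTOTAXIS",), ("ANTI_PHOTOTAXIS",), ("RANDOM_WALK",)],
        # continuation chosen by 4 of 5 alternatives (mean ~5 rules per
        # controller, matching the 4-11 rules of competent evolved
        # foragers)
        "<rules>": [
            ("<rule>",),
            ("<rule>", "<rules>"),
            ("<rule>", "<rules>"),
            ("<rule>", "<rules>"),
            ("<rule>", "<rules>"),
        ],
        "<rule>": [("RULE", "<conds>", "WHILE", "<bset>", "THEN", "<acts>", "END")],
        "<conds>": [("<cond>",), ("<cond>", "<conds>")],
        "<cond>": [("<var>", "<bool>")],
        "<var>": [(v,) for v in _VARS],
        "<bool>": [("True",), ("False",)],
        "<bset>": [(b,) for b in _BSETS],
        "<acts>": [("<act>",), ("<act>", "<acts>"), ("<act>", "<acts>")],
        # the two item actions carry the same total weight as the three
        # behavior switches; memory writes fill the rest
        "<atype>": [
            ("behavior:PHOTOTAXIS",),
            ("behavior:ANTI_PHOTOTAXIS",),
            ("behavior:RANDOM_WALK",),
            ("pickup",),
            ("pickup",),
            ("drop",),
            ("drop",),
            ("set:want_pickup:set_true",),
            ("set:want_pickup:set_false",),
            ("set:M1:inc",),
            ("set:M1:dec",),
            ("set:M2:inc",),
            ("set:M2:dec",),
        ],
        "<act>": [("<atype>", "<prob>")],
        "<prob>": [(f"p{k}",) for k in range(1, 21)],
    },
    start="<ruleset>",
)


def _tokens_to_ruleset(tokens) -> RuleSet:
    """Assemble a RuleSet from a terminal token stream of the grammar."""
    initial_behavior = "RANDOM_WALK"
    if tokens and tokens[0] == "INIT":
        initial_behavior = tokens[1]
        tokens = tokens[2:]
    rules = []
    i = 0
    n = len(tokens)
    while i < n:
        assert tokens[i] == "RULE", tokens[i]
        i += 1
        conds = []
        seen = {}
        while tokens[i] != "WHILE":
            var, val = tokens[i], tokens[i + 1] == "True"
            seen[var] = val  # contradictory duplicates: last occurrence wins
            i += 2
        conds = tuple(seen.items())
        i += 1  # WHILE
        behaviors = _BSET_MAP[tokens[i]]
        i += 1
        assert tokens[i] == "THEN"
        i += 1
        actions = []
        while tokens[i] != "END":
            atype = tokens[i]
            prob = PROB_GRID[int(tokens[i + 1][1:]) - 1]
            if atype.startswith("behavior:"):
                actions.append(("set_behavior", atype.split(":")[1], prob))
            elif atype == "pickup":
                actions.append(("pickup", prob))
            elif atype == "drop":
                actions.append(("drop", prob))
            else:
                _, var, op = atype.split(":")
                actions.append(("set_state", var, op, prob))
            i += 2
        i += 1  # END
        rules.append(Rule(conds, behaviors, tuple(actions)))
    return RuleSet(tuple(rules), initial_behavior=initial_behavior, name="evolved")


def map_genotype(
    genotype,
    grammar: Grammar = CONTROLLER_GRAMMAR,
    max_wraps: int = 3,
) -> RuleSet | None:
    """Map an integer-codon genotype to a RuleSet (``None`` = invalid)."""
    tokens = derive(grammar, genotype, max_wraps=max_wraps)
    if tokens is None:
        return None
    if grammar is CONTROLLER_GRAMMAR:
        rs = _tokens_to_ruleset(tokens)
        if validate_ruleset(rs):  # pragma: no cover - grammar guarantees validity
            return None
        return rs
    raise ValueError("map_genotype builds RuleSets only for the controller grammar")


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------


def random_genotype(rng: np.random.Generator, min_len: int = 20, max_len: int = 100) -> list[int]:
    n = int(rng.integers(min_len, max_len + 1))
    return list(map(int, rng.integers(0, CODON_MAX + 1, size=n)))


def crossover(
    parent1,
    parent2,
    rng: np.random.Generator,
    probability: float = 0.3,
    max_len: int = 500,
):
    """Variable-length single-point crossover.

    With ``probability`` an independent cut point is chosen in each
    parent and the tails are exchanged; otherwise the children are
    copies.  Children are truncated to ``max_len`` codons.
    """
    p1, p2 = list(parent1), list(parent2)
    if rng.random() < probability and len(p1) >= 2 and len(p2) >= 2:
        k1 = int(rng.integers(1, len(p1)))
        k2 = int(rng.integers(1, len(p2)))
        c1 = p1[:k1] + p2[k2:]
        c2 = p2[:k2] + p1[k1:]
    else:
        c1, c2 = p1[:], p2[:]
    return c1[:max_len], c2[:max_len]


def mutate(genotype, rng: np.random.Generator, probability: float = 0.05) -> list[int]:
    """Per-codon uniform resampling with the given probability."""
    out = list(genotype)
    mask = rng.random(len(out)) < probability
    if mask.any():
        vals = rng.integers(0, CODON_MAX + 1, size=int(mask.sum()))
        j = 0
        for i in range(len(out)):
            if mask[i]:
                out[i] = int(vals[j])
                j += 1
    return out


def select_parent(population, fitnesses, rng: np.random.Generator):
    """Roulette-wheel draw proportional to fitness.

    All-zero fitness (typical of the earliest generations, where random
    controllers barely forage) falls back to a uniform draw.
    """
    f = np.asarray(fitnesses, dtype=float)
    if (f < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total <= 0:
        i = int(rng.integers(0, len(population)))
    else:
        u = rng.random() * total
        c = np.cumsum(f)
        i = int(np.searchsorted(c, u, side="right"))
        i = min(i, len(population) - 1)
    return population[i]


# ---------------------------------------------------------------------------
# fitness evaluation
# ---------------------------------------------------------------------------


def _eval_seed(*parts) -> int:
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def evaluate_genotype(
    genotype,
    arena: ArenaConfig,
    team_size: int = 4,
    evaluations: int = 3,
    T: float = 5000.0,
    seed: int = 0,
    dt: float = 0.1,
    grammar: Grammar = CONTROLLER_GRAMMAR,
    max_wraps: int = 3,
) -> float:
    """Mean delivered-item count of a homogeneous team; invalid -> 0."""
    rs = map_genotype(genotype, grammar, max_wraps=max_wraps)
    if rs is None:
        return 0.0
    controllers = [rs] * team_size
    total = 0.0
    for e in range(evaluations):
        trace = run_episode(
            arena, controllers, T=T, dt=dt, seed=_eval_seed(seed, e), record_events=False
        )
        total += trace.delivered_count
    return total / evaluations


def _post_evaluate(rs: RuleSet, arena, team_size, evaluations, T, dt, seed):
    """Specialization and speed of a controller (event-recording runs)."""
    specs, speeds = [], []
    for e in range(evaluations):
        tr = run_episode(
            arena, [rs] * team_size, T=T, dt=dt, seed=_eval_seed(seed, 7919, e)
        )
        specs.append(specialization_degree(tr))
        speeds.append(mean_linear_speed(tr))
    specs = [s for s in specs if not np.isnan(s)]
    return (float(np.mean(specs)) if specs else float("nan"), float(np.mean(speeds)))


# ---------------------------------------------------------------------------
# the evolutionary loop
# ---------------------------------------------------------------------------


@dataclass
class EvolutionConfig:
    """GA settings; the defaults are the full-scale experiment."""

    population_size: int = 100
    team_size: int = 4
    generations: int = 2000
    evaluations: int = 3
    T: float = 5000.0
    dt: float = 0.1
    crossover_prob: float = 0.3
    mutation_prob: float = 0.05
    elitism: float = 0.05
    seed: int = 0
    min_init_len: int = 60
    max_init_len: int = 300
    max_len: int = 500
    max_wraps: int = 3

    def __post_init__(self):
        for name in ("crossover_prob", "mutation_prob", "elitism"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")

    @property
    def n_elite(self) -> int:
        return int(round(self.elitism * self.population_size))

    @classmethod
    def desk(cls, **overrides) -> "EvolutionConfig":
        """Desk-scale profile: pop 30, 200 generations, 2 evaluations, 2000 s."""
        base = dict(population_size=30, generations=200, evaluations=2, T=2000.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class EvolutionHistory:
    """Per-generation record of one evolutionary run."""

    config: EvolutionConfig
    arena: ArenaConfig
    df: pd.DataFrame = field(repr=False)
    genotypes: list = field(default_factory=list, repr=False)  # best of each generation
    best_ever_genotype: list = None
    best_ever_fitness: float = 0.0

    @property
    def best_ruleset(self) -> RuleSet | None:
        if self.best_ever_genotype is None:
            return None
        return map_genotype(self.best_ever_genotype, max_wraps=self.config.max_wraps)


def evolve(config: EvolutionConfig, arena: ArenaConfig, progress: bool = False, workers: int = 1) -> EvolutionHistory:
    """Run one seeded evolutionary experiment.

    Per-genotype evaluation seeds are derived from ``(run seed,
    generation, slot index)``, so fitness values do not depend on the
    order (or parallel schedule) in which genotypes are evaluated; with
    ``workers > 1`` genotypes of a generation are evaluated in parallel
    processes with identical results.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x6A]))
    population = [
        random_genotype(rng, config.min_init_len, config.max_init_len)
        for _ in range(config.population_size)
    ]

    def fitness_of(genotype, gen, idx):
        return evaluate_genotype(
            genotype,
            arena,
            team_size=config.team_size,
            evaluations=config.evaluations,
            T=config.T,
            seed=_eval_seed(config.seed, gen, idx),
            dt=config.dt,
            max_wraps=config.max_wraps,
        )

    if workers > 1:
        from joblib import Parallel, delayed

        pool = Parallel(n_jobs=workers, backend="loky")
    else:
        pool = None

    rows = []
    best_genotypes = []
    _post_cache: dict = {}
    best_ever_fit = -1.0
    best_ever_geno = None
    best_ever_spec = float("nan")
    best_ever_speed = float("nan")
    for gen in range(config.generations):
        if pool is not None:
            fits = pool(
                delayed(fitness_of)(g, gen, i) for i, g in enumerate(population)
            )
        else:
            fits = [fitness_of(g, gen, i) for i, g in enumerate(population)]
        fits = np.asarray(fits, dtype=float)
        order = np.argsort(-fits, kind="stable")
        best_idx = int(order[0])
        best_fit = float(fits[best_idx])
        best_geno = list(population[best_idx])
        rs = map_genotype(best_geno, max_wraps=config.max_wraps)
        # post-evaluate the generation's best for specialization and speed;
        # skipped while nothing is delivered (both metrics are undefined or
        # uninformative for non-foraging controllers)
        if rs is not None and best_fit > 0:
            key = tuple(best_geno)
            if key not in _post_cache:
                _post_cache[key] = _post_evaluate(
                    rs, arena, config.team_size, config.evaluations, config.T,
                    config.dt, _eval_seed(config.seed, gen),
                )
            spec, speed = _post_cache[key]
            n_rules = rs.n_rules
        else:
            spec, speed = float("nan"), float("nan")
            n_rules = rs.n_rules if rs is not None else 0
        if best_fit > best_ever_fit:
            best_ever_fit = best_fit
            best_ever_geno = best_geno
            best_ever_spec = spec
            best_ever_speed = speed
        rows.append(
            {
                "generation": gen,
                "best_fitness": best_fit,
                "mean_fitness": float(fits.mean()),
                "best_specialization": spec,
                "best_speed_pct": speed,
                "best_n_rules": n_rules,
                "best_ever_fitness": best_ever_fit,
                "best_ever_specialization": best_ever_spec,
                "best_ever_speed_pct": best_ever_speed,
            }
        )
        best_genotypes.append(best_geno)
        if progress:
            print(
                f"gen {gen:4d}  best {best_fit:7.1f}  mean {fits.mean():7.1f}  "
                f"spec {spec:5.2f}  speed {speed:5.1f}%  rules {n_rules}"
            )

        if gen == config.generations - 1:
            break
        # generational replacement with elitism
        nxt = [list(population[int(i)]) for i in order[: config.n_elite]]
        while len(nxt) < config.population_size:
            p1 = select_parent(population, fits, rng)
            p2 = select_parent(population, fits, rng)
            c1, c2 = crossover(
                p1, p2, rng, probability=config.crossover_prob, max_len=config.max_len
            )
            nxt.append(mutate(c1, rng, config.mutation_prob))
            if len(nxt) < config.population_size:
                nxt.append(mutate(c2, rng, config.mutation_prob))
        population = nxt

    return EvolutionHistory(
        config=config,
        arena=arena,
        df=pd.DataFrame(rows),
        genotypes=best_genotypes,
        best_ever_genotype=best_ever_geno,
        best_ever_fitness=best_ever_fit,
    )
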