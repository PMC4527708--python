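"""Exhaustive fitness-landscape search over strategy compositions.

With three pre-adapted roles (dropper, collector, generalist) and a team
of ``n`` robots, the composition space is the discrete simplex of
``C(n+2, 2)`` mixes.  Every mix is evaluated with seeded replicate
episodes (common random numbers across mixes, so comparisons between
compositions are paired) and the landscape's argmax and discrete
steepest-ascent phase portrait are derived from the mean fitness table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .sim import run_episode
from .strategies import make_strategy
from .world import ArenaConfig

__all__ = [
    "StrategyMix",
    "MixResult",
    "LandscapeResult",
    "enumerate_mixes",
    "evaluate_mix",
    "build_landscape",
    "phase_portrait",
]


class StrategyMix(NamedTuple):
    """Counts of each role in a team."""

    droppers: int
    collectors: int
    generalists: int

    @property
    def team_size(self) -> int:
        return self.droppers + self.collectors + self.generalists

    def controllers(self) -> list:
        """Role-ordered controller list (droppers first, then collectors)."""
        d = make_strategy("dropper")
        c = make_strategy("collector")
        g = make_strategy("generalist")
        return [d] * self.droppers + [c] * self.collectors + [g] * self.generalists


@dataclass
class MixResult:
    mix: StrategyMix
    mean: float
    sd: float
    values: np.ndarray

    @property
    def sd_defined(self) -> bool:
        return self.values.size > 1


def enumerate_mixes(team_size: int) -> list[StrategyMix]:
    """All compositions of ``team_size`` robots into the three roles.

    Deterministic lexicographic order in (droppers, collectors); the
    count is the stars-and-bars number C(team_size+2, 2).
    """
    if team_size < 1:
        raise ValueError("team_size must be >= 1")
    out = []
    for d in range(team_size + 1):
        for c in range(team_size + 1 - d):
            out.append(StrategyMix(d, c, team_size - d - c))
    return out


def _replicate_seed(base_seed: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(rep)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def evaluate_mix(
    mix,
    arena: ArenaConfig,
    replicates: int = 10,
    T: float = 5000.0,
    base_seed: int = 0,
    dt: float = 0.1,
) -> MixResult:
    """Mean group fitness of one composition over seeded replicates.

    Replicate ``r`` of every mix shares the episode seed derived from
    ``(base_seed, r)``, so mixes are compared under common random numbers.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mix = StrategyMix(*mix)
    controllers = mix.controllers()
    vals = np.empty(replicates)
    for r in range(replicates):
        trace = run_episode(
            arena,
            controllers,
            T=T,
            dt=dt,
            seed=_replicate_seed(base_seed, r),
            record_events=False,
        )
        vals[r] = trace.delivered_count
    sd = float(np.std(vals, ddof=1)) if replicates > 1 else 0.0
    return MixResult(mix=mix, mean=float(vals.mean()), sd=sd, values=vals)


@dataclass
class LandscapeResult:
    """Full landscape: per-mix statistics, argmax and phase portrait."""

    arena: ArenaConfig
    team_size: int
    replicates: int
    T: float
    table: pd.DataFrame = field(repr=False)
    argmax: StrategyMix = None
    vectors: dict = field(default_factory=dict, repr=False)

    def mean_of(self, mix) -> float:
        mix = StrategyMix(*mix)
        row = self.table[
            (self.table.droppers == mix.droppers)
            & (self.table.collectors == mix.collectors)
            & (self.table.generalists == mix.generalists)
        ]
        return float(row["mean"].iloc[0])


def build_landscape(
    arena: ArenaConfig,
    team_size: int = 4,
    replicates: int = 10,
    T: float = 5000.0,
    base_seed: int = 0,
    dt: float = 0.1,
    progress: bool = False,
) -> LandscapeResult:
    """Evaluate every composition and assemble the landscape."""
    mixes = enumerate_mixes(team_size)
    rows = []
    for m in mixes:
        res = evaluate_mix(m, arena, replicates=replicates, T=T, base_seed=base_seed, dt=dt)
        rows.append(
            {
                "droppers": m.droppers,
                "collectors": m.collectors,
                "generalists": m.generalists,
                "mean": res.mean,
                "sd": res.sd,
                "sd_defined": res.sd_defined,
                **{f"rep{j}": v for j, v in enumerate(res.values)},
            }
        )
        if progress:
            print(f"  mix {m}: {res.mean:.1f} +- {res.sd:.1f}")
    table = pd.DataFrame(rows)
    best_idx = int(table["mean"].idxmax())  # ties: first in enumeration order
    argmax = StrategyMix(
        int(table.loc[best_idx, "droppers"]),
        int(table.loc[best_idx, "collectors"]),
        int(table.loc[best_idx, "generalists"]),
    )
    result = LandscapeResult(
        arena=arena,
        team_size=team_size,
        replicates=replicates,
        T=T,
        table=table,
        argmax=argmax,
    )
    result.vectors = phase_portrait(result)
    return result


def _neighbors(mix: StrategyMix) -> list[tuple[StrategyMix, tuple[int, int, int]]]:
    """One-robot reassignments between two roles, with their simplex step."""
    out = []
    counts = list(mix)
    for a in range(3):
        if counts[a] == 0:
            continue
        for b in range(3):
            if a == b:
                continue
            step = [0, 0, 0]
            step[a] -= 1
            step[b] += 1
            nxt = StrategyMix(*(c + s for c, s in zip(counts, step)))
            out.append((nxt, tuple(step)))
    return out


def phase_portrait(landscape: LandscapeResult) -> dict:
    """Discrete steepest-ascent vector at every composition.

    Each mix points along the one-robot reassignment with the greatest
    mean-fitness increase; local optima carry the zero vector.  This is
    the discrete analogue of a selection gradient on the mix simplex.
    """
    means = {
        StrategyMix(int(r.droppers), int(r.collectors), int(r.generalists)): float(r["mean"])
        for _, r in landscape.table.iterrows()
    }
    vectors = {}
    for mix, mean in means.items():
        best_gain = 0.0
        best_step = (0, 0, 0)
        for nxt, step_vec in _neighbors(mix):
            gain = means.get(nxt, -np.inf) - mean
            if gain > best_gain:
                best_gain = gain
                best_step = step_vec
        vectors[mix] = best_step
    return vectors


def greedy_ascent(landscape: LandscapeResult, start) -> list[StrategyMix]:
    """Follow the phase portrait from ``start`` until a local optimum."""
    path = [StrategyMix(*start)]
    seen = {path[0]}
    while True:
        step_vec = landscape.vectors.get(path[-1], (0, 0, 0))
        if step_vec == (0, 0, 0):
            return path
        nxt = StrategyMix(*(c + s for c, s in zip(path[-1], step_vec)))
        if nxt in seen:  # cycle guard; cannot happen on a strictly improving path
            return path
        path.append(nxt)
        seen.add(nxt)
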