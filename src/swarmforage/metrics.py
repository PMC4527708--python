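"""Quantitative read-outs of foraging episodes.

* **fitness** — group performance: items delivered to the nest within
  the episode.
* **degree of task specialization** — the fraction of delivered items
  that passed through the hands of more than one robot (a robot counts
  as a handler of an item if it picked it up at least once; gravity
  transport down the slope adds no handler).
* **mean linear speed** — the average absolute per-interval speed along
  the arena's long axis, as a percentage of the 0.15 m/s nominal flat
  speed cap.
* density maps, cache-size series, an OLS regression of fitness on
  specialization and speed, and the 4-to-20-robot scalability ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import run_episode
from .world import RunTrace, make_arena

__all__ = [
    "MetricsResult",
    "fitness",
    "specialization_degree",
    "mean_linear_speed",
    "density_map",
    "regress_fitness",
    "scalability_ratio",
    "ScalabilityResult",
    "compute_metrics",
]


def fitness(trace: RunTrace) -> int:
    """Number of items delivered to the nest (deliver events)."""
    if len(trace.events):
        n = int((trace.events["event"] == "deliver").sum())
        return n
    return int(trace.delivered_count)


def specialization_degree(trace: RunTrace) -> float:
    """Fraction of delivered items handled by two or more robots.

    Returns ``nan`` when nothing was delivered (undefined).
    """
    handlers = trace.handler_sets()
    if not handlers:
        return float("nan")
    multi = sum(1 for h in handlers.values() if len(h) >= 2)
    return multi / len(handlers)


def mean_linear_speed(trace: RunTrace, v_max: float | None = None) -> float:
    """Mean |dx|/dt over robots and snapshot intervals, % of the cap.

    The theoretical maximum is the nominal flat-ground speed
    (``arena.speed_flat``, 0.15 m/s by default); the faster downhill
    coast is a transient aid and is not used as the reference.
    """
    if trace.n_snapshots < 2:
        raise ValueError("need at least two snapshots to measure speed")
    v_max = v_max if v_max is not None else trace.arena.speed_flat
    dx = np.abs(np.diff(trace.snap_x, axis=0))
    dt = np.diff(trace.snap_t)
    speed = dx / dt[:, None]
    return float(speed.mean() / v_max * 100.0)


def density_map(
    traces,
    x_bins: int = 40,
    time_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robot occupancy histogram over (x, time), averaged over traces.

    Returns ``(H, x_edges, t_edges)`` where ``H`` has shape
    ``(x_bins, time_bins)`` and every time-bin column sums to 1.
    """
    if isinstance(traces, RunTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    arena = traces[0].arena
    x_edges = np.linspace(0.0, arena.length, x_bins + 1)
    T = max(tr.snap_t[-1] for tr in traces)
    t_edges = np.linspace(0.0, T, time_bins + 1)
    H = np.zeros((x_bins, time_bins))
    for tr in traces:
        for r in range(tr.n_robots):
            h, _, _ = np.histogram2d(
                tr.snap_x[:, r], tr.snap_t, bins=(x_edges, t_edges)
            )
            H += h
    col = H.sum(axis=0, keepdims=True)
    col[col == 0] = 1.0
    return H / col, x_edges, t_edges


@dataclass
class RegressionResult:
    params: dict
    bse: dict
    pvalues: dict
    rsquared: float
    n: int
    flags: list
    sm_results: object

    def __getitem__(self, k):
        return self.params[k]


def regress_fitness(specialization, speed, fit) -> RegressionResult:
    """OLS of group fitness on specialization degree and mean speed.

    One observation per evolutionary run / controller; degenerate or
    collinear predictors are flagged rather than raised.
    """
    import statsmodels.api as sm

    spec = np.asarray(specialization, dtype=float)
    spd = np.asarray(speed, dtype=float)
    y = np.asarray(fit, dtype=float)
    if not (spec.shape == spd.shape == y.shape) or spec.ndim != 1:
        raise ValueError("predictors and response must be 1-D and equally long")
    if spec.size < 3:
        raise ValueError("need at least 3 observations")
    flags = []
    X = np.column_stack([spec, spd])
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(spec), X])) < 3:
        flags.append("collinear or constant predictors")
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = ["const", "specialization", "speed"]
    return RegressionResult(
        params=dict(zip(names, res.params)),
        bse=dict(zip(names, res.bse)),
        pvalues=dict(zip(names, res.pvalues)),
        rsquared=float(res.rsquared),
        n=int(spec.size),
        flags=flags,
        sm_results=res,
    )


@dataclass
class ScalabilityResult:
    ratio: float
    small_mean: float
    large_mean: float
    small_values: np.ndarray
    large_values: np.ndarray
    defined: bool


def _scaled_controllers(controller, n: int):
    from .landscape import StrategyMix
    from .rules import RuleSet

    if isinstance(controller, RuleSet):
        return [controller] * n
    mix = StrategyMix(*controller)
    if n % mix.team_size:
        raise ValueError(f"cannot scale mix {tuple(mix)} to {n} robots")
    f = n // mix.team_size
    return StrategyMix(mix.droppers * f, mix.collectors * f, mix.generalists * f).controllers()


def scalability_ratio(
    controller,
    small_n: int = 4,
    large_n: int = 20,
    reps: int = 5,
    T: float = 5000.0,
    seed: int = 0,
    environment: str = "sloped",
    dt: float = 0.1,
    scale_mode: str = "width",
) -> ScalabilityResult:
    """Fitness ratio of a controller at ``large_n`` robots vs ``small_n``.

    The large team forages in an arena grown in direct proportion to the
    team.  With the default ``scale_mode="width"`` the corridor widens by
    ``large_n / small_n`` (area proportional to robots) while every
    travel leg keeps its length — the regime in which near-linear
    scaling of group performance is geometrically possible.
    ``scale_mode="both"`` instead multiplies length and width; every leg
    then lengthens by the scale factor and throughput per robot drops
    accordingly.  Source item density is held constant in either mode.

    ``controller`` is either a single RuleSet applied homogeneously or a
    role mix scaled proportionally.  The ratio is undefined (nan) when
    the small team's mean fitness is zero.
    """
    scale = large_n / small_n
    small_arena = make_arena(environment, 1.0)
    if scale_mode == "width":
        large_arena = make_arena(
            environment,
            1.0,
            width=small_arena.width * scale,
            n_source_items=int(round(small_arena.n_source_items * scale)),
        )
    elif scale_mode == "both":
        large_arena = make_arena(environment, scale)
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    small_ctrl = _scaled_controllers(controller, small_n)
    large_ctrl = _scaled_controllers(controller, large_n)
    sv = np.empty(reps)
    lv = np.empty(reps)
    for r in range(reps):
        s = int(np.random.SeedSequence([int(seed), r]).generate_state(1)[0] & 0x7FFFFFFF)
        sv[r] = run_episode(small_arena, small_ctrl, T=T, dt=dt, seed=s, record_events=False).delivered_count
        lv[r] = run_episode(large_arena, large_ctrl, T=T, dt=dt, seed=s, record_events=False).delivered_count
    sm_, lm = float(sv.mean()), float(lv.mean())
    if sm_ == 0.0:
        return ScalabilityResult(float("nan"), sm_, lm, sv, lv, defined=False)
    return ScalabilityResult(lm / sm_, sm_, lm, sv, lv, defined=True)


@dataclass
class MetricsResult:
    """Bundle of the per-trace read-outs."""

    fitness: int
    specialization_degree: float
    mean_speed_pct: float
    cache_size_series: np.ndarray

    def as_dict(self) -> dict:
        return {
            "fitness": self.fitness,
            "specialization_degree": self.specialization_degree,
            "mean_speed_pct": self.mean_speed_pct,
        }


def compute_metrics(trace: RunTrace) -> MetricsResult:
    return MetricsResult(
        fitness=fitness(trace),
        specialization_degree=specialization_degree(trace),
        mean_speed_pct=mean_linear_speed(trace),
        cache_size_series=trace.cache_size,
    )
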