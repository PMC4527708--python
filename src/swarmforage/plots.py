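"""Figures: ternary fitness landscapes, density maps, evolution history.

The ternary landscape uses a plain simplex-to-plane projection
(x = c + g/2, y = g*sqrt(3)/2 for a composition (d, c, g) normalized to
1); arrows show the discrete steepest-ascent phase portrait and the
black dot marks the optimum.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_ternary_landscape", "plot_density_map", "plot_history", "plot_trajectory"]

_SQ3 = math.sqrt(3.0)


def _project(d, c, g, n):
    return (c + g / 2.0) / n, (g * _SQ3 / 2.0) / n


def plot_ternary_landscape(landscape, ax=None, cmap="viridis"):
    """Group performance over the composition simplex (one point per mix)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    tab = landscape.table
    n = landscape.team_size
    xs, ys = _project(tab.droppers.values, tab.collectors.values, tab.generalists.values, n)
    sc = ax.scatter(xs, ys, c=tab["mean"].values, s=600, cmap=cmap, zorder=2, edgecolor="k")
    for mix, vec in landscape.vectors.items():
        if vec == (0, 0, 0):
            continue
        x0, y0 = _project(*mix, n)
        x1, y1 = _project(*(m + v for m, v in zip(mix, vec)), n)
        ax.annotate(
            "",
            xy=(x0 + 0.55 * (x1 - x0), y0 + 0.55 * (y1 - y0)),
            xytext=(x0 + 0.2 * (x1 - x0), y0 + 0.2 * (y1 - y0)),
            arrowprops=dict(arrowstyle="->", color="0.25", lw=1.2),
            zorder=3,
        )
    bx, by = _project(*landscape.argmax, n)
    ax.scatter([bx], [by], c="k", s=90, zorder=4, label=f"optimum {tuple(landscape.argmax)}")
    for (xx, yy, lab, ha) in (
        (0.0, -0.04, "all droppers", "center"),
        (1.0, -0.04, "all collectors", "center"),
        (0.5, _SQ3 / 2 + 0.03, "all generalists", "center"),
    ):
        ax.text(xx, yy, lab, ha=ha, va="center", fontsize=9)
    ax.plot([0, 1, 0.5, 0], [0, 0, _SQ3 / 2, 0], color="0.6", lw=1, zorder=1)
    plt.colorbar(sc, ax=ax, label="items delivered (mean)")
    ax.set_axis_off()
    ax.set_title(
        f"{landscape.arena.environment} arena, {landscape.team_size} robots, "
        f"{landscape.replicates} reps x {landscape.T:.0f}s"
    )
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_density_map(H, x_edges, t_edges, arena=None, ax=None):
    """Occupancy density over arena position (x) and time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    im = ax.pcolormesh(t_edges, x_edges, H, cmap="magma", shading="auto")
    plt.colorbar(im, ax=ax, label="occupancy (column-normalized)")
    if arena is not None:
        for e in arena.zone_edges:
            ax.axhline(e, color="w", lw=0.7, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("x position (m)")
    return ax


def plot_history(history, ax=None):
    """Fitness and specialization of the best controller per generation."""
    df = history.df
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sc = ax.scatter(
        df.generation, df.best_specialization, c=df.best_fitness, cmap="viridis", s=12
    )
    plt.colorbar(sc, ax=ax, label="group fitness")
    ax.plot(df.generation, df.best_ever_specialization, color="0.4", lw=1, label="best-ever")
    ax.set_xlabel("generation")
    ax.set_ylabel("degree of task specialization")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_trajectory(trace, robot: int | None = None, ax=None):
    """x-position of each robot over time, with the cache size below."""
    if ax is None:
        _, (ax, ax2) = plt.subplots(
            2, 1, figsize=(7, 5), sharex=True, height_ratios=[3, 1]
        )
    else:
        ax2 = None
    robots = range(trace.n_robots) if robot is None else [robot]
    for r in robots:
        ax.plot(trace.snap_t, trace.snap_x[:, r], lw=0.7, label=f"robot {r}")
    for e in trace.arena.zone_edges:
        ax.axhline(e, color="0.7", lw=0.6, ls="--")
    ax.set_ylabel("x (m)")
    ax.legend(fontsize=7, ncol=4)
    if ax2 is not None:
        ax2.plot(trace.snap_t, trace.cache_size, color="tab:orange", lw=1)
        ax2.set_ylabel("cache size")
        ax2.set_xlabel("time (s)")
    return ax
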