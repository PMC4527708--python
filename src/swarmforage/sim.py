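"""Discrete-time episode simulation.

The control loop runs at ``dt = 0.1 s``.  Each step processes robots in
fixed id order (sense -> rule scan -> item actions -> motion with
obstacle avoidance), then item sliding and source replenishment.  Robot
motion is a unicycle: the heading turns toward the steering target at at
most 1.5 rad/s and the linear speed is the zone/direction speed cap
scaled by the heading alignment ``max(0, cos(error))``, so a robot
reversing direction rotates roughly in place like a differential-drive
platform rather than arcing onward.

``run_episode`` is a pure function of ``(arena, controllers, T, dt,
seed)``; the same arguments reproduce the event log bit for bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _engine
from ._engine import BODY_RADIUS, PICKUP_RADIUS, advance
from .rules import RW_DWELL_MAX, RW_DWELL_MIN, CompiledTeam, RuleSet, compile_team
from .world import (
    ArenaConfig,
    ConfigurationError,
    EVENT_NAMES,
    RunTrace,
    STATUS_AT_SOURCE,
    STATUS_CARRIED,
    STATUS_DELIVERED,
    STATUS_IN_CACHE,
    STATUS_ON_GROUND,
    STATUS_SLIDING,
    WorldState,
    ZONES,
    init_world,
)

__all__ = [
    "SimulationFault",
    "robot_speed",
    "step",
    "slide_items",
    "apply_item_actions",
    "replenish_source",
    "run_episode",
    "percepts_for",
    "PICKUP_RADIUS",
    "BODY_RADIUS",
]

DEFAULT_DT = 0.1
DEFAULT_SNAPSHOT_STRIDE = 10  # record positions every 1 s at the default dt

#: RANDOM_WALK dwell-time range (s); single source of truth in swarmforage.rules
RW_DWELL = (RW_DWELL_MIN, RW_DWELL_MAX)


class SimulationFault(RuntimeError):
    """Non-finite state or exhausted resources inside the simulator."""


# ---------------------------------------------------------------------------
# speed model
# ---------------------------------------------------------------------------


def robot_speed(arena: ArenaConfig, zone, direction_of_travel: str = "flat", behavior=None) -> float:
    """Speed cap (m/s) for motion in ``zone`` travelling in the given direction.

    Only the slope zone of a sloped arena differentiates direction:
    ascending (toward the source, +x) is capped at ``speed_up``,
    descending at ``speed_down``.  ``behavior`` does not affect the cap
    and is accepted only for interface completeness.
    """
    if isinstance(zone, str):
        if zone not in ZONES:
            raise ValueError(f"unknown zone {zone!r}")
        zi = ZONES.index(zone)
    else:
        zi = int(zone)
        if not 0 <= zi <= 3:
            raise ValueError(f"zone index {zi} out of range")
    if arena.sloped and zi == 2:
        if direction_of_travel in ("up", "ascending", "+x"):
            return arena.speed_up
        if direction_of_travel in ("down", "descending", "-x"):
            return arena.speed_down
        return arena.speed_flat
    return arena.speed_flat


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------

_EMPTY_F = np.zeros((0, 0))
_EMPTY_I8 = np.zeros((0, 0), dtype=np.int8)
_EMPTY_I64 = np.zeros((0, 0), dtype=np.int64)
_EMPTY_T = np.zeros(0)
_EMPTY_CACHE = np.zeros(0, dtype=np.int64)


def _call_kernel(
    world: WorldState,
    team: CompiledTeam,
    n_steps: int,
    dt: float,
    start_step: int = 0,
    ev_bufs=None,
    snap_bufs=None,
    stride: int = DEFAULT_SNAPSHOT_STRIDE,
    rw_dwell: tuple[float, float] | None = None,
) -> int:
    a = world.arena
    e0, e1, e2 = a.zone_edges
    dwell_lo, dwell_hi = rw_dwell if rw_dwell is not None else RW_DWELL
    if ev_bufs is None:
        ev_bufs = _alloc_events(1)
        record_events = False
    else:
        record_events = True
    if snap_bufs is None:
        snap_bufs = (_EMPTY_T, _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_I8, _EMPTY_I64, _EMPTY_CACHE)
        record_snaps = False
    else:
        record_snaps = True
    rng_arr = world.rng.state_array()
    status = advance(
        n_steps,
        dt,
        start_step,
        a.length,
        a.width,
        e0,
        e1,
        e2,
        a.sloped,
        a.speed_flat,
        a.speed_up,
        a.speed_down,
        a.item_slide_speed,
        dwell_lo,
        dwell_hi,
        world.rx,
        world.ry,
        world.rheading,
        world.rbehavior,
        world.rcarry,
        world.rstate,
        world.rw_heading,
        world.rw_timer,
        team.rule_lo,
        team.rule_hi,
        team.pre,
        team.bmask,
        team.act_off,
        team.act_type,
        team.act_arg,
        team.act_prob,
        world.item_x,
        world.item_y,
        world.item_status,
        world.item_carrier,
        world.floor_next,
        world.floor_prev,
        world.slide_ids,
        world.meta,
        world.t,
        rng_arr,
        record_events,
        *ev_bufs,
        record_snaps,
        stride,
        *snap_bufs,
    )
    world.rng.state = int(rng_arr[0])
    return int(status)


def _alloc_events(cap: int):
    return (
        np.zeros(cap),
        np.zeros(cap, dtype=np.int64),
        np.zeros(cap, dtype=np.int8),
        np.zeros(cap, dtype=np.int64),
        np.zeros(cap),
        np.zeros(cap),
    )


def _events_frame(ev_bufs, n: int) -> pd.DataFrame:
    ev_t, ev_item, ev_code, ev_robot, ev_x, ev_y = ev_bufs
    return pd.DataFrame(
        {
            "t": ev_t[:n].copy(),
            "item_id": ev_item[:n].copy(),
            "event": np.array(EVENT_NAMES)[ev_code[:n]],
            "robot_id": ev_robot[:n].copy(),
            "x": ev_x[:n].copy(),
            "y": ev_y[:n].copy(),
        }
    )


def _resolve_team(world: WorldState, controllers) -> CompiledTeam:
    if isinstance(controllers, CompiledTeam):
        return controllers
    if isinstance(controllers, RuleSet):
        controllers = [controllers] * world.n_robots
    if len(controllers) != world.n_robots:
        raise ConfigurationError(
            f"need {world.n_robots} controllers, got {len(controllers)}"
        )
    key = tuple(id(c) for c in controllers)
    cache = getattr(world, "_team_cache", None)
    if cache is None or cache[0] != key:
        team = compile_team(controllers)
        world._team_cache = (key, team)
    return world._team_cache[1]


def percepts_for(world: WorldState, robot: int):
    """Build the :class:`~swarmforage.rules.Percepts` of one robot."""
    from .rules import Percepts
    from .world import STATUS_SLIDING

    r = int(robot)
    x, y = float(world.rx[r]), float(world.ry[r])
    nearby = False
    for j in world.floor_items():
        if world.item_status[j] == STATUS_SLIDING:
            continue
        if (world.item_x[j] - x) ** 2 + (world.item_y[j] - y) ** 2 <= PICKUP_RADIUS**2:
            nearby = True
            break
    return Percepts(
        zone=world.arena.zone_of(x),
        carrying=bool(world.rcarry[r] >= 0),
        light_direction=(1.0, 0.0),
        nearby_item=nearby,
    )


def step(world: WorldState, controllers, dt: float = DEFAULT_DT) -> WorldState:
    """Advance the world by one control step (in place; returns the world).

    Item events raised during the step are appended to
    ``world.event_log`` as ``(t, item_id, event, robot_id, x, y)``.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    team = _resolve_team(world, controllers)
    world.ensure_capacity(world.n_spawned + world.n_robots + 8)
    ev = _alloc_events(8 * max(1, world.n_robots))
    n0 = int(world.meta[5])
    world.meta[5] = 0
    status = _call_kernel(world, team, 1, dt, ev_bufs=ev)
    n = int(world.meta[5])
    for i in range(n):
        world.event_log.append(
            (
                float(ev[0][i]),
                int(ev[1][i]),
                EVENT_NAMES[int(ev[2][i])],
                int(ev[3][i]),
                float(ev[4][i]),
                float(ev[5][i]),
            )
        )
    world.meta[5] = n0 + n
    if status == _engine.STATUS_NAN:
        raise SimulationFault("non-finite robot state encountered")
    if status == _engine.STATUS_CAPACITY:
        raise SimulationFault("item capacity exhausted")
    return world


# ---------------------------------------------------------------------------
# Python-level item operations (the kernel inlines the same semantics)
# ---------------------------------------------------------------------------


def slide_items(world: WorldState, dt: float = DEFAULT_DT) -> WorldState:
    """Move sliding items downslope at ``item_slide_speed``.

    Items cross the slope/cache boundary, stop just past it with a small
    deterministic-stream jitter, and become ``in_cache``.
    """
    a = world.arena
    if not a.sloped:
        raise ConfigurationError("slide_items requires a sloped arena")
    e1 = a.zone_edges[1]
    s = 0
    while s < int(world.meta[3]):
        i = int(world.slide_ids[s])
        world.item_x[i] -= a.item_slide_speed * dt
        if world.item_x[i] < e1:
            u1 = world.rng.next_float()
            u2 = world.rng.next_float()
            world.item_x[i] = e1 - 0.05 - 0.15 * u1
            world.item_y[i] = min(max(world.item_y[i] + (u2 - 0.5) * 0.2, 0.1), a.width - 0.1)
            world.item_status[i] = STATUS_IN_CACHE
            world.meta[4] += 1
            world.event_log.append(
                (world.time, i, "slide_stop", -1, float(world.item_x[i]), float(world.item_y[i]))
            )
            world.meta[3] -= 1
            world.slide_ids[s] = world.slide_ids[world.meta[3]]
        else:
            s += 1
    return world


def replenish_source(world: WorldState) -> WorldState:
    """Top the source zone back up to ``n_source_items`` items."""
    a = world.arena
    have = int(np.count_nonzero(world.item_status[: world.n_spawned] == STATUS_AT_SOURCE))
    for _ in range(a.n_source_items - have):
        world.spawn_source_item()
    return world


def apply_item_actions(world: WorldState, robot: int, action: str) -> WorldState:
    """Attempt a pickup or drop for one robot.

    Violated preconditions (nothing in range, not carrying, ...) make the
    action a silent no-op.  Pickups from the source trigger immediate
    replenishment; drops in the slope zone of a sloped arena start the
    item sliding; drops in the nest deliver.
    """
    r = int(robot)
    x, y = float(world.rx[r]), float(world.ry[r])
    a = world.arena
    e0, e1, e2 = a.zone_edges
    if action == "pickup":
        if world.rcarry[r] >= 0:
            return world
        best, bd = -1, PICKUP_RADIUS**2
        for j in world.floor_items():
            if world.item_status[j] == STATUS_SLIDING:
                continue  # sliding items move too fast to grasp
            d2 = (world.item_x[j] - x) ** 2 + (world.item_y[j] - y) ** 2
            if d2 < bd:
                bd, best = d2, j
        if best < 0:
            return world
        was_source = world.item_status[best] == STATUS_AT_SOURCE
        if world.item_status[best] == STATUS_IN_CACHE:
            world.meta[4] -= 1
        world.floor_remove(best)
        world.item_status[best] = STATUS_CARRIED
        world.item_carrier[best] = r
        world.rcarry[r] = best
        world.event_log.append(
            (world.time, best, "pickup", r, float(world.item_x[best]), float(world.item_y[best]))
        )
        if was_source:
            world.ensure_capacity(world.n_spawned + 1)
            replenish_source(world)
    elif action == "drop":
        it = int(world.rcarry[r])
        if it < 0:
            return world
        world.item_x[it] = x
        world.item_y[it] = y
        world.item_carrier[it] = -1
        world.rcarry[r] = -1
        if x < e0:
            world.item_status[it] = STATUS_DELIVERED
            world.meta[1] += 1
            world.event_log.append((world.time, it, "deliver", r, x, y))
        elif a.sloped and e1 <= x < e2:
            world.item_status[it] = STATUS_SLIDING
            world.slide_ids[world.meta[3]] = it
            world.meta[3] += 1
            world.floor_insert(it)
            world.event_log.append((world.time, it, "drop", r, x, y))
        else:
            world.item_status[it] = STATUS_ON_GROUND
            world.floor_insert(it)
            world.event_log.append((world.time, it, "drop", r, x, y))
    else:
        raise ValueError(f"unknown item action {action!r}")
    return world


# ---------------------------------------------------------------------------
# whole episodes
# ---------------------------------------------------------------------------


def run_episode(
    arena: ArenaConfig,
    controllers,
    T: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    snapshot_stride: int = DEFAULT_SNAPSHOT_STRIDE,
    record_events: bool = True,
    rw_dwell: tuple[float, float] | None = None,
) -> RunTrace:
    """Simulate one seeded episode and return its trace.

    ``controllers`` is one RuleSet per robot (or a single shared
    RuleSet plus ``n_robots`` via a list).  With ``record_events=False``
    only snapshots, cache size and the delivered count are kept, which
    is considerably faster for fitness-only evaluations.
    """
    if T <= 0:
        raise ConfigurationError("T must be > 0")
    if isinstance(controllers, RuleSet):
        raise ConfigurationError("pass a list with one controller per robot")
    n_robots = len(controllers)
    n_steps = int(round(T / dt))
    team = compile_team(controllers)

    capacity = arena.n_source_items + 512
    max_capacity = arena.n_source_items + (n_steps // 2 + 1) * n_robots + 8
    while True:
        world = init_world(
            arena, n_robots, seed, controllers=controllers, item_capacity=capacity
        )
        if record_events:
            ev_cap = min(2 * n_robots * n_steps, 1_000_000) + 64
            ev = _alloc_events(ev_cap)
        else:
            ev = None
        n_snap = n_steps // snapshot_stride + 1
        snap = (
            np.zeros(n_snap),
            np.zeros((n_snap, n_robots)),
            np.zeros((n_snap, n_robots)),
            np.zeros((n_snap, n_robots)),
            np.zeros((n_snap, n_robots), dtype=np.int8),
            np.zeros((n_snap, n_robots), dtype=np.int64),
            np.zeros(n_snap, dtype=np.int64),
        )
        # snapshot 0 is the initial state
        snap[0][0] = 0.0
        snap[1][0] = world.rx
        snap[2][0] = world.ry
        snap[3][0] = world.rheading
        snap[4][0] = world.rbehavior
        snap[5][0] = world.rcarry
        world.meta[7] = 1
        status = _call_kernel(
            world, team, n_steps, dt, ev_bufs=ev, snap_bufs=snap,
            stride=snapshot_stride, rw_dwell=rw_dwell,
        )
        if status == _engine.STATUS_CAPACITY and capacity < max_capacity:
            capacity = min(capacity * 4, max_capacity)
            continue
        break
    if status == _engine.STATUS_NAN:
        raise SimulationFault("non-finite robot state encountered")
    if status == _engine.STATUS_CAPACITY:
        raise SimulationFault("item capacity exhausted")

    n_ev = int(world.meta[5]) if record_events else 0
    events = _events_frame(ev, n_ev) if record_events else _events_frame(_alloc_events(1), 0)
    n_snap_written = int(world.meta[7])
    return RunTrace(
        arena=arena,
        T=T,
        dt=dt,
        seed=seed,
        snap_t=snap[0][:n_snap_written],
        snap_x=snap[1][:n_snap_written],
        snap_y=snap[2][:n_snap_written],
        snap_heading=snap[3][:n_snap_written],
        snap_behavior=snap[4][:n_snap_written],
        snap_carrying=snap[5][:n_snap_written],
        events=events,
        delivered_count=int(world.meta[1]),
        cache_size=snap[6][:n_snap_written],
        events_truncated=bool(world.meta[6]),
    )
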