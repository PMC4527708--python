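"""Episode simulator: speeds, item mechanics, determinism, invariants."""

import math

import numpy as np
import pytest

from swarmforage import (
    RuleSet,
    SimulationFault,
    apply_item_actions,
    init_world,
    make_arena,
    replenish_source,
    robot_speed,
    run_episode,
    slide_items,
    step,
)
from swarmforage.rules import Rule
from swarmforage.world import (
    BODY_RADIUS,
    STATUS_AT_SOURCE,
    STATUS_CARRIED,
    STATUS_IN_CACHE,
    STATUS_ON_GROUND,
    STATUS_SLIDING,
)

B_ALL = frozenset({"PHOTOTAXIS", "ANTI_PHOTOTAXIS", "RANDOM_WALK"})
IDLE = RuleSet(())  # no rules: robots keep random-walking, touch nothing


def _pickup_forever():
    return RuleSet((Rule((("carrying", False),), B_ALL, (("pickup", 1.0),)),))


class TestRobotSpeed:
    @pytest.mark.parametrize(
        "env,zone,direction,expected",
        [
            ("sloped", "nest", "up", 0.15),
            ("sloped", "slope", "ascending", 0.015),
            ("sloped", "slope", "descending", 0.23),
            ("sloped", "slope", "lateral", 0.15),
            ("sloped", "source", "down", 0.15),
            ("flat", "slope", "ascending", 0.15),
        ],
    )
    def test_speed_caps(self, env, zone, direction, expected):
        assert robot_speed(make_arena(env), zone, direction) == pytest.approx(expected)

    def test_unknown_zone_rejected(self, sloped_arena):
        with pytest.raises(ValueError):
            robot_speed(sloped_arena, "summit", "up")


class TestSlideItems:
    def test_slope_drop_slides_to_cache_at_one_meter_per_second(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        e1, e2 = sloped_arena.zone_edges[1], sloped_arena.zone_edges[2]
        mid = (e1 + e2) / 2
        k = w.spawn_source_item()
        w.item_x[k], w.item_y[k] = mid, 0.9
        w.item_status[k] = STATUS_SLIDING
        w.slide_ids[0] = k
        w.meta[3] = 1
        t, dt = 0.0, 0.1
        while w.item_status[k] == STATUS_SLIDING:
            slide_items(w, dt)
            t += dt
            assert t < 10.0
        # distance/speed: (mid - e1) m at 1 m/s
        assert t == pytest.approx((mid - e1) / 1.0, abs=0.2)
        assert w.item_status[k] == STATUS_IN_CACHE
        assert w.item_x[k] < e1

    def test_flat_arena_never_slides(self, flat_arena):
        from swarmforage import ConfigurationError

        w = init_world(flat_arena, 1, seed=0)
        with pytest.raises(ConfigurationError):
            slide_items(w)


class TestApplyItemActions:
    def test_drop_in_nest_delivers(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        k = w.spawn_source_item()
        w.floor_remove(k)
        w.item_status[k] = STATUS_CARRIED
        w.item_carrier[k] = 0
        w.rcarry[0] = k
        w.rx[0], w.ry[0] = 0.5, 0.5
        apply_item_actions(w, 0, "drop")
        assert w.delivered_count == 1
        assert w.event_log[-1][2] == "deliver"

    def test_drop_in_nest_zone_of_flat_arena_also_delivers(self, flat_arena):
        w = init_world(flat_arena, 1, seed=0)
        k = w.spawn_source_item()
        w.floor_remove(k)
        w.item_status[k] = STATUS_CARRIED
        w.rcarry[0] = k
        w.rx[0], w.ry[0] = 1.0, 0.5
        apply_item_actions(w, 0, "drop")
        assert w.delivered_count == 1

    def test_slope_drop_starts_sliding_only_when_sloped(self, sloped_arena, flat_arena):
        for arena, expected in ((sloped_arena, STATUS_SLIDING), (flat_arena, STATUS_ON_GROUND)):
            w = init_world(arena, 1, seed=0)
            k = w.spawn_source_item()
            w.floor_remove(k)
            w.item_status[k] = STATUS_CARRIED
            w.rcarry[0] = k
            w.rx[0] = (arena.zone_edges[1] + arena.zone_edges[2]) / 2
            apply_item_actions(w, 0, "drop")
            assert w.item_status[k] == expected

    def test_pickup_out_of_range_is_noop(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        w.rx[0], w.ry[0] = 0.5, 0.5  # nest; items are at the source
        n_events = len(w.event_log)
        apply_item_actions(w, 0, "pickup")
        assert w.rcarry[0] == -1
        assert len(w.event_log) == n_events

    def test_source_pickup_triggers_replenishment(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        w.rx[0] = w.item_x[0]
        w.ry[0] = w.item_y[0]
        apply_item_actions(w, 0, "pickup")
        assert w.rcarry[0] == 0
        assert w.status_counts()["at_source"] == 5
        assert w.n_spawned == 6

    def test_sliding_items_cannot_be_grasped(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        k = w.spawn_source_item()
        w.item_status[k] = STATUS_SLIDING
        w.item_x[k], w.item_y[k] = 5.0, 0.9
        w.slide_ids[0] = k
        w.meta[3] = 1
        w.rx[0], w.ry[0] = 5.0, 0.9
        apply_item_actions(w, 0, "pickup")
        assert w.rcarry[0] == -1

    def test_pickup_tiebreak_lower_robot_id_wins(self, sloped_arena):
        """Two robots in range of one item in the same step."""
        a = make_arena("sloped", 1, n_source_items=0)
        w = init_world(a, 2, seed=0)
        k = w.spawn_source_item()
        w.item_x[k], w.item_y[k] = 0.8, 0.8
        w.item_status[k] = STATUS_ON_GROUND
        w.rx[0], w.ry[0] = 0.7, 0.8
        w.rx[1], w.ry[1] = 0.9, 0.8
        grab = _pickup_forever()
        step(w, [grab, grab])
        assert w.rcarry[0] == k
        assert w.rcarry[1] == -1

    def test_three_simultaneous_pickups_three_replacements(self, sloped_arena):
        w = init_world(sloped_arena, 3, seed=0)
        for r in range(3):
            w.rx[r] = w.item_x[r]
            w.ry[r] = w.item_y[r]
        grab = _pickup_forever()
        step(w, [grab] * 3)
        assert sorted(int(c) for c in w.rcarry) == [0, 1, 2]
        assert w.status_counts()["at_source"] == 5
        assert w.n_spawned == 8


class TestReplenish:
    def test_topup_count(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        # remove two source items out of band
        for k in (0, 1):
            w.floor_remove(k)
            w.item_status[k] = STATUS_ON_GROUND
            w.item_x[k] = 0.5
            w.floor_insert(k)
        replenish_source(w)
        assert w.status_counts()["at_source"] == 5

    def test_no_spawn_when_full(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        replenish_source(w)
        assert w.n_spawned == 5


class TestStepAndEpisode:
    def test_climb_speed_advance(self, sloped_arena):
        """A phototaxing robot aligned with +x on the slope gains 0.015 m/s."""
        photo = RuleSet(
            (Rule((), B_ALL, (("set_behavior", "PHOTOTAXIS", 1.0),)),),
            initial_behavior="PHOTOTAXIS",
        )
        w = init_world(sloped_arena, 1, seed=0)
        w.rx[0] = (sloped_arena.zone_edges[1] + sloped_arena.zone_edges[2]) / 2
        w.ry[0] = sloped_arena.width / 2
        w.rheading[0] = 0.0
        x0 = w.rx[0]
        for _ in range(10):  # 1 s
            step(w, [photo])
        assert w.rx[0] - x0 == pytest.approx(0.015, rel=0.05)

    def test_step_equals_batched_episode(self, sloped_arena, roles):
        """Stepping one tick at a time reproduces the batched kernel run."""
        controllers = [roles["dropper"], roles["collector"]]
        T, dt = 60.0, 0.1
        trace = run_episode(sloped_arena, controllers, T=T, dt=dt, seed=11)
        w = init_world(sloped_arena, 2, seed=11, controllers=controllers)
        for _ in range(int(T / dt)):
            step(w, controllers, dt)
        final = trace.snap_x[-1], trace.snap_y[-1]
        assert w.rx == pytest.approx(final[0], abs=1e-12)
        assert w.ry == pytest.approx(final[1], abs=1e-12)
        ev = trace.events
        assert len(w.event_log) == len(ev)
        for logged, (_, row) in zip(w.event_log, ev.iterrows()):
            assert logged[2] == row["event"]
            assert logged[1] == row["item_id"]
            assert logged[0] == pytest.approx(row["t"], abs=1e-9)

    def test_episode_determinism(self, sloped_arena, roles):
        team = [roles["dropper"]] * 2 + [roles["collector"]] * 2
        t1 = run_episode(sloped_arena, team, T=300, seed=42)
        t2 = run_episode(sloped_arena, team, T=300, seed=42)
        assert t1.delivered_count == t2.delivered_count
        assert np.array_equal(t1.snap_x, t2.snap_x)
        assert t1.events.equals(t2.events)

    def test_idle_controllers_deliver_nothing(self, sloped_arena):
        tr = run_episode(sloped_arena, [IDLE] * 2, T=100, seed=0)
        assert tr.delivered_count == 0

    def test_no_robots_world_items_still_slide(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        k = w.spawn_source_item()
        w.item_x[k] = 5.0
        w.item_status[k] = STATUS_SLIDING
        w.slide_ids[0] = k
        w.meta[3] = 1
        slide_items(w, 0.1)
        assert w.item_x[k] == pytest.approx(4.9)

    def test_nan_state_aborts(self, sloped_arena):
        w = init_world(sloped_arena, 1, seed=0)
        w.rx[0] = float("nan")
        with pytest.raises(SimulationFault):
            step(w, [IDLE])

    def test_smoke_generalists_deliver(self, sloped_arena, roles):
        tr = run_episode(sloped_arena, [roles["generalist"]] * 4, T=5000, seed=9,
                         record_events=False)
        assert tr.delivered_count > 0


class TestInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_conservation_and_speed_cap_random_episodes(self, sloped_arena, roles, seed):
        """Item conservation and displacement caps on random short episodes."""
        rng = np.random.default_rng(seed)
        n_robots = int(rng.integers(1, 5))
        names = list(roles)
        team = [roles[names[int(rng.integers(3))]] for _ in range(n_robots)]
        env = "sloped" if rng.random() < 0.7 else "flat"
        arena = make_arena(env)
        T = float(rng.integers(30, 120))
        tr = run_episode(arena, team, T=T, seed=int(rng.integers(2**31)))
        ev = tr.events
        n_source_picks = 0
        if len(ev):
            picks = ev[ev["event"] == "pickup"]
            n_source_picks = int((picks["x"] >= arena.zone_edges[2]).sum())
        assert tr.delivered_count == (ev["event"] == "deliver").sum()
        # per-snapshot displacement <= fastest cap * interval (+ tolerance
        # for the collision slide-off)
        dx = np.abs(np.diff(tr.snap_x, axis=0))
        dy = np.abs(np.diff(tr.snap_y, axis=0))
        dt_snap = np.diff(tr.snap_t)[:, None]
        vmax = max(arena.speed_flat, arena.speed_down)
        assert (np.hypot(dx, dy) <= vmax * dt_snap + 4 * BODY_RADIUS).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_no_overlap_after_crowded_episode(self, seed, roles):
        arena = make_arena("sloped")
        team = [roles["collector"]] * 4  # all four crowd the cache
        tr = run_episode(arena, team, T=200, seed=seed)
        x, y = tr.snap_x, tr.snap_y
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.hypot(x[:, i] - x[:, j], y[:, i] - y[:, j])
                assert (d >= 2 * BODY_RADIUS - 1e-6).all()

    def test_conservation_counts_inside_stepped_world(self, sloped_arena, roles):
        w = init_world(sloped_arena, 3, seed=5, controllers=[roles["generalist"]] * 3)
        for _ in range(2000):
            step(w, [roles["generalist"]] * 3)
        w.check_invariants()
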