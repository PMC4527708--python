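"""Metric worked examples and statistical read-outs."""

import numpy as np
import pytest

from swarmforage import make_arena, make_fixture_trace, run_episode
from swarmforage.metrics import (
    density_map,
    fitness,
    mean_linear_speed,
    regress_fitness,
    scalability_ratio,
    specialization_degree,
)


def _chain(item, t0, handlers, deliver_by=None):
    """Scripted pickup(->drop->pickup...)->deliver chain for one item."""
    rows = []
    t = t0
    for h in handlers[:-1]:
        rows.append((t, item, "pickup", h))
        rows.append((t + 1, item, "drop", h))
        t += 2
    last = handlers[-1]
    rows.append((t, item, "pickup", last))
    rows.append((t + 1, item, "deliver", deliver_by if deliver_by is not None else last))
    return rows


class TestFitness:
    def test_empty_trace(self):
        assert fitness(make_fixture_trace([])) == 0

    def test_counts_deliver_events(self):
        rows = []
        for i in range(7):
            rows += _chain(i, 10 * i, [0])
        assert fitness(make_fixture_trace(rows)) == 7

    def test_matches_simulator_counter(self, sloped_arena, roles):
        team = [roles["dropper"], roles["dropper"], roles["collector"], roles["collector"]]
        tr = run_episode(sloped_arena, team, T=1500, seed=3)
        assert fitness(tr) == tr.delivered_count


class TestSpecializationDegree:
    def test_all_partitioned_is_one(self):
        rows = []
        for i in range(4):
            rows += _chain(i, 10 * i, [0, 1])
        assert specialization_degree(make_fixture_trace(rows)) == 1.0

    def test_single_generalist_is_zero(self):
        rows = []
        for i in range(5):
            rows += _chain(i, 10 * i, [2])
        assert specialization_degree(make_fixture_trace(rows)) == 0.0

    def test_three_of_five_multi_handled(self):
        rows = []
        for i in range(3):
            rows += _chain(i, 10 * i, [0, 1])
        for i in (3, 4):
            rows += _chain(i, 100 + 10 * i, [1])
        assert specialization_degree(make_fixture_trace(rows)) == pytest.approx(0.6)

    def test_undefined_without_deliveries(self):
        tr = make_fixture_trace([(0.0, 1, "pickup", 0)])
        assert np.isnan(specialization_degree(tr))

    def test_repeated_pickup_by_same_robot_is_one_handler(self):
        rows = [
            (0.0, 1, "pickup", 0),
            (1.0, 1, "drop", 0),
            (2.0, 1, "pickup", 0),
            (3.0, 1, "deliver", 0),
        ]
        assert specialization_degree(make_fixture_trace(rows)) == 0.0


class TestMeanLinearSpeed:
    def _trace(self, xs, dt=1.0):
        xs = np.asarray(xs, dtype=float)
        return make_fixture_trace(
            [], snapshots={"t": np.arange(len(xs)) * dt, "x": xs.reshape(-1, 1)}
        )

    def test_stationary_zero(self):
        assert mean_linear_speed(self._trace([2.0] * 50)) == 0.0

    def test_full_speed_hundred_percent(self):
        xs = np.arange(0, 30) * 0.15  # 0.15 m per 1 s interval
        assert mean_linear_speed(self._trace(xs)) == pytest.approx(100.0)

    def test_half_duty_cycle_fifty_percent(self):
        xs = [0.0]
        for i in range(40):
            xs.append(xs[-1] + (0.15 if i % 2 == 0 else 0.0))
        assert mean_linear_speed(self._trace(xs)) == pytest.approx(50.0)

    def test_absolute_value_of_backward_motion(self):
        xs = np.concatenate([np.arange(0, 10) * 0.15, np.arange(8, -1, -1) * 0.15])
        assert mean_linear_speed(self._trace(xs)) == pytest.approx(100.0)

    def test_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            mean_linear_speed(make_fixture_trace([]))


class TestDensityMap:
    def test_parked_in_nest_all_mass_in_nest_bins(self, sloped_arena):
        t = np.arange(0, 100.0)
        x = np.full((100, 3), 0.7)
        tr = make_fixture_trace([], arena=sloped_arena, snapshots={"t": t, "x": x})
        H, xe, te = density_map(tr, x_bins=20, time_bins=5)
        nest_bins = xe[1:] <= sloped_arena.zone_edges[0] + 1e-9
        assert H[nest_bins].sum() == pytest.approx(5.0)  # all columns

    def test_columns_normalized_on_simulated_episode(self, sloped_arena, roles):
        tr = run_episode(sloped_arena, [roles["generalist"]] * 2, T=300, seed=1)
        H, _, _ = density_map(tr)
        assert H.sum(axis=0) == pytest.approx(np.ones(H.shape[1]))

    def test_late_time_bimodality_under_partitioning(self, sloped_arena, roles):
        """2 droppers + 2 collectors segregate: late-time density mass sits
        on both sides of the slope, little on the slope itself."""
        team = [roles["dropper"]] * 2 + [roles["collector"]] * 2
        traces = [run_episode(sloped_arena, team, T=3000, seed=s) for s in (1, 2)]
        H, xe, te = density_map(traces, x_bins=39, time_bins=6)
        e1, e2 = sloped_arena.zone_edges[1], sloped_arena.zone_edges[2]
        centers = (xe[:-1] + xe[1:]) / 2
        late = H[:, -1]
        below = late[centers < e1].sum()
        on_slope = late[(centers >= e1) & (centers < e2)].sum()
        above = late[centers >= e2].sum()
        assert below > 0.3 and above > 0.3
        assert on_slope < below and on_slope < above


class TestRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        spec = rng.uniform(0, 1, 22)
        speed = np.full(22, 30.0)
        fit = 10 + 120 * spec
        res = regress_fitness(spec, speed, fit)
        assert res.params["specialization"] == pytest.approx(120.0)
        assert res.flags  # constant speed flagged as degenerate

    def test_known_slopes_recovered_within_2_se(self):
        rng = np.random.default_rng(1)
        n = 22
        spec = rng.uniform(0, 1, n)
        speed = rng.uniform(10, 35, n)
        fit = 20 + 90 * spec + 2.5 * speed + rng.normal(0, 8, n)
        res = regress_fitness(spec, speed, fit)
        assert abs(res.params["specialization"] - 90) < 2 * res.bse["specialization"]
        assert abs(res.params["speed"] - 2.5) < 2 * res.bse["speed"]

    def test_permutation_false_positive_rate(self):
        """With labels permuted, 'significant' slopes appear at ~alpha."""
        rng = np.random.default_rng(2)
        n = 22
        spec = rng.uniform(0, 1, n)
        speed = rng.uniform(10, 35, n)
        fit = 20 + 90 * spec + 2.5 * speed + rng.normal(0, 8, n)
        hits = 0
        reps = 400
        for _ in range(reps):
            res = regress_fitness(spec, speed, rng.permutation(fit))
            if res.pvalues["specialization"] < 0.05:
                hits += 1
        assert hits / reps < 0.10

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            regress_fitness([0.1, 0.2], [1, 2], [3, 4])


class TestScalabilityRatio:
    def test_identical_sizes_ratio_one(self):
        res = scalability_ratio((2, 2, 0), small_n=4, large_n=4, reps=2, T=1200, seed=0)
        assert res.ratio == pytest.approx(1.0)

    def test_idle_controller_undefined(self):
        from swarmforage import RuleSet

        res = scalability_ratio(RuleSet(()), small_n=4, large_n=8, reps=1, T=100, seed=0)
        assert not res.defined
        assert np.isnan(res.ratio)

    def test_indivisible_mix_rejected(self):
        with pytest.raises(ValueError):
            scalability_ratio((2, 1, 1), small_n=4, large_n=10, reps=1, T=50, seed=0)
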