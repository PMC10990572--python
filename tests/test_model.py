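"""Tracking-model unit tests: maps, searches, unitary process, ticks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mottrack import EnvironmentConfig, ModelParams, simulate_trajectory
from mottrack.model import (AttentionMap, ObjectMap, RoundRobinState,
                            UnitaryBuffer, attention_tick,
                            confusion_ratio, kth_nearest_object_location,
                            nearest_object_location, rasterize,
                            resolve_claims, run_model_on_trajectory,
                            select_unitary_lock,
                            unitary_selection_probabilities,
                            unitary_extrapolate)


def sparse_map(cells, grid=(50, 50)):
    counts = {}
    for c in cells:
        counts[c] = counts.get(c, 0) + 1
    return ObjectMap(counts, grid)


def brute_force_nearest(o, origin, nob=math.inf):
    """Dense-grid oracle replicating the documented ring-scan tie-break."""
    best, best_key = None, None
    for cell, cnt in o.cells.items():
        dr, dc = cell[0] - origin[0], cell[1] - origin[1]
        key = (dr * dr + dc * dc, max(abs(dr), abs(dc)), cell[0], cell[1])
        if key[0] <= nob * nob and (best_key is None or key < best_key):
            best, best_key = cell, key
    return best


class TestRasterize:
    def test_conservation(self):
        o = rasterize([[1.5, 2.5], [10.0, 20.0], [30.2, 7.7]], (50, 50))
        assert o.n_objects == 3
        assert o.grid.sum() == 3

    def test_same_cell_accumulates(self):
        o = rasterize([[5.2, 7.9], [5.8, 7.1]], (50, 50))
        assert o.count_at((7, 5)) == 2

    def test_floor_convention(self):
        o = rasterize([[5.9, 7.1]], (50, 50))
        assert o.count_at((7, 5)) == 1

    def test_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            rasterize([[50.0, 10.0]], (50, 50))
        with pytest.raises(ValueError):
            rasterize([[-0.1, 10.0]], (50, 50))


class TestNearestSearch:
    def test_origin_itself_occupied(self):
        o = sparse_map([(10, 10), (20, 20)])
        assert nearest_object_location(o, (10, 10), 100) == (10, 10)

    def test_empty_map_aborts(self):
        o = sparse_map([])
        assert nearest_object_location(o, (5, 5), 10) is None

    def test_beyond_bound_aborts(self):
        o = sparse_map([(0, 0)])
        assert nearest_object_location(o, (30, 30), nob=10) is None
        assert nearest_object_location(o, (30, 30), nob=math.inf) == (0, 0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        cells = [tuple(map(int, rng.integers(0, 50, 2))) for _ in range(n)]
        o = sparse_map(cells)
        origin = tuple(map(int, rng.integers(0, 50, 2)))
        nob = float(rng.choice([5, 15, 40, math.inf]))
        assert nearest_object_location(o, origin, nob) == \
            brute_force_nearest(o, origin, nob)

    @pytest.mark.parametrize("seed", range(20))
    def test_kth_matches_sorted_distance_list(self, seed):
        rng = np.random.default_rng(100 + seed)
        cells = [tuple(map(int, rng.integers(0, 40, 2))) for _ in range(8)]
        o = sparse_map(cells)
        origin = tuple(map(int, rng.integers(0, 40, 2)))
        ordered = sorted(
            o.cells,
            key=lambda c: ((c[0] - origin[0]) ** 2 + (c[1] - origin[1]) ** 2,
                           max(abs(c[0] - origin[0]), abs(c[1] - origin[1])),
                           c[0], c[1]))
        expanded = [c for c in ordered for _ in range(o.cells[c])]
        for k in range(1, 6):
            expected = expanded[k - 1] if k <= len(expanded) else None
            assert kth_nearest_object_location(o, origin, k) == expected

    def test_k1_reduces_to_nearest(self):
        o = sparse_map([(3, 4), (10, 2), (20, 20)])
        assert kth_nearest_object_location(o, (0, 0), 1) == \
            nearest_object_location(o, (0, 0), math.inf)

    def test_insufficient_objects_gives_none(self):
        o = sparse_map([(3, 4)])
        assert kth_nearest_object_location(o, (0, 0), 2) is None

    def test_multiplicity_counts_ranks(self):
        o = sparse_map([(5, 5), (5, 5), (9, 9)])
        assert kth_nearest_object_location(o, (5, 5), 2) == (5, 5)
        assert kth_nearest_object_location(o, (5, 5), 3) == (9, 9)


class TestConfusionRatio:
    def test_equal_distances_give_one(self):
        o = sparse_map([(0, 10), (0, -10 % 50)])  # use symmetric cells
        o = sparse_map([(10, 20), (10, 0)])
        for c_e in (0.5, 1.0, 4.0, math.inf):
            assert confusion_ratio(o, (10, 10), c_e) == pytest.approx(1.0)

    def test_direct_substitution(self):
        o = sparse_map([(10, 11), (10, 12)])  # d1=1, d2=2 from (10,10)
        assert confusion_ratio(o, (10, 10), 1.0) == pytest.approx(0.5)
        assert confusion_ratio(o, (10, 10), 2.0) == pytest.approx(0.25)

    def test_large_exponent_limit(self):
        o = sparse_map([(10, 11), (10, 12)])
        assert confusion_ratio(o, (10, 10), 100.0) < 1e-20
        assert confusion_ratio(o, (10, 10), math.inf) == 0.0

    def test_zero_first_distance_is_unambiguous(self):
        o = sparse_map([(10, 10), (10, 20)])
        assert confusion_ratio(o, (10, 10), 1.0) == 0.0

    def test_fewer_than_two_objects_signalled(self):
        o = sparse_map([(10, 10)])
        with pytest.raises(ValueError):
            confusion_ratio(o, (5, 5), 1.0)


class TestSelectionProbabilities:
    def test_already_normalized_passthrough(self):
        np.testing.assert_allclose(
            unitary_selection_probabilities([0.2, 0.8]), [0.2, 0.8])

    def test_all_zero_falls_back_to_uniform(self):
        np.testing.assert_allclose(
            unitary_selection_probabilities([0.0, 0.0, 0.0, 0.0]),
            [0.25] * 4)

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1,
                    max_size=8),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_sums_to_one_and_scale_invariant(self, ratios, scale):
        p = unitary_selection_probabilities(ratios)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()
        p_scaled = unitary_selection_probabilities(
            [r * scale for r in ratios])
        np.testing.assert_allclose(p, p_scaled, rtol=1e-9, atol=1e-12)


class TestUnitaryLock:
    def setup_maps(self):
        # thread 0 crowded (two close objects), thread 1 isolated
        o = sparse_map([(10, 11), (10, 13), (40, 11), (40, 30)])
        a = AttentionMap([(10, 10), (40, 10)], (50, 50))
        return a, o

    def test_refractory_period_blocks_reselection(self):
        a, o = self.setup_maps()
        params = ModelParams(f_loc=10.0, f_u=10.0)
        rng = np.random.default_rng(0)
        u = select_unitary_lock(a, o, UnitaryBuffer(), params, now=0.0,
                                rng=rng)
        assert u.locked_tid is not None
        u2 = select_unitary_lock(a, o, u, params, now=0.05, rng=rng)
        assert u2 is u  # 50 ms < 1/f_u = 100 ms

    def test_argmax_rule_under_infinite_exponent(self):
        a, o = self.setup_maps()
        params = ModelParams(f_loc=10.0, f_u=10.0, c_e=math.inf)
        u = select_unitary_lock(a, o, UnitaryBuffer(), params, now=0.0,
                                rng=np.random.default_rng(0))
        assert u.locked_tid == 0  # most confusable: d1/d2 = 1/3 vs 1/20

    def test_lock_switch_discards_buffer(self):
        a, o = self.setup_maps()
        params = ModelParams(f_loc=10.0, f_u=10.0, c_e=math.inf)
        u = UnitaryBuffer(u=(1, 1), v=(2, 2), locked_tid=1, lock_time=-1.0)
        u2 = select_unitary_lock(a, o, u, params, now=0.0,
                                 rng=np.random.default_rng(0))
        assert u2.locked_tid == 0
        assert u2.u is None and u2.v is None

    def test_reselection_of_incumbent_retains_buffer(self):
        a, o = self.setup_maps()
        params = ModelParams(f_loc=10.0, f_u=10.0, c_e=math.inf)
        u = UnitaryBuffer(u=(1, 1), v=(2, 2), locked_tid=0, lock_time=-1.0)
        u2 = select_unitary_lock(a, o, u, params, now=0.0,
                                 rng=np.random.default_rng(0))
        assert u2.locked_tid == 0
        assert u2.u == (1, 1) and u2.v == (2, 2)


class TestUnitaryExtrapolate:
    def test_zero_velocity(self):
        u = UnitaryBuffer(u=(5, 5), v=(5, 5))
        assert unitary_extrapolate(u, (9, 9), (50, 50)) == (9, 9)

    def test_vector_arithmetic(self):
        u = UnitaryBuffer(u=(10, 10), v=(10, 7))
        assert unitary_extrapolate(u, (10, 10), (50, 50)) == (10, 13)

    def test_clipped_to_grid(self):
        u = UnitaryBuffer(u=(48, 48), v=(40, 40))
        assert unitary_extrapolate(u, (48, 48), (50, 50)) == (49, 49)

    def test_incomplete_buffer_rejected(self):
        with pytest.raises(ValueError):
            unitary_extrapolate(UnitaryBuffer(u=(1, 1)), (0, 0), (50, 50))

    def test_constant_velocity_prediction_beats_decoy(self):
        """After two updates of a locked thread following an object moving
        +2 columns per update, the extrapolated search origin coincides with
        the object's true next cell, so the thread ignores a decoy that is
        nearer to its stale location."""
        params = ModelParams(f_loc=10.0, f_u=100.0, nob=10.0)
        a = AttentionMap([(10, 10)], (50, 50))
        u = UnitaryBuffer(locked_tid=0, lock_time=0.0)
        rng = np.random.default_rng(0)
        sched = RoundRobinState()
        # two moves fill the buffer: (10,12) then (10,14)
        for col in (12, 14):
            ev = attention_tick(a, sparse_map([(10, col)]), u, params,
                                sched, rng)
            assert ev.kind == "moved"
        assert u.full and u.u == (10, 14) and u.v == (10, 12)
        # object truly at (10,16); decoy at (10,13) is nearer to the stale
        # attended cell (10,14) but farther from the extrapolated origin
        ev = attention_tick(a, sparse_map([(10, 16), (10, 13)]), u, params,
                            sched, rng)
        assert ev.kind == "moved"
        assert a.attended_list == [(10, 16)]


class TestAttentionTick:
    def test_static_object_confirmed_in_place(self):
        o = sparse_map([(10, 10), (30, 30)])
        a = AttentionMap([(10, 10)], (50, 50))
        ev = attention_tick(a, o, UnitaryBuffer(), ModelParams(f_loc=10.0),
                            RoundRobinState(), np.random.default_rng(0))
        assert ev.kind == "confirmed"
        assert a.attended_list == [(10, 10)]

    def test_moved_object_reacquired_within_bound(self):
        o = sparse_map([(10, 13), (40, 40)])
        a = AttentionMap([(10, 10)], (50, 50))
        ev = attention_tick(a, o, UnitaryBuffer(),
                            ModelParams(f_loc=10.0, nob=24.0),
                            RoundRobinState(), np.random.default_rng(0))
        assert ev.kind == "moved"
        assert a.attended_list == [(10, 13)]

    def test_object_beyond_bound_drops_location(self):
        o = sparse_map([(40, 40)])
        a = AttentionMap([(10, 10), (40, 40)], (50, 50))
        ev = attention_tick(a, o, UnitaryBuffer(),
                            ModelParams(f_loc=10.0, nob=5.0),
                            RoundRobinState(), np.random.default_rng(0))
        assert ev.kind == "dropped"
        assert len(a) == 1

    def test_zero_lag_property(self):
        """Immediately after its tick, a location's cell is occupied or the
        location was dropped."""
        rng = np.random.default_rng(5)
        env = EnvironmentConfig(
            dynamics_kind="ou", sigma=4.0, arena=(80.0, 80.0),
            updates_per_second=10.0, n_updates=30, n_targets=3, n_objects=6)
        traj = simulate_trajectory(env, seed=8)
        params = ModelParams(f_loc=20.0, nob=10.0)
        from mottrack.model import rasterize as rast
        a = AttentionMap(
            [(int(traj.frames[0][j, 1]), int(traj.frames[0][j, 0]))
             for j in traj.target_mask], (80, 80))
        sched = RoundRobinState()
        u = UnitaryBuffer()
        for f in range(traj.n_frames):
            if len(a) == 0:
                break
            o = rast(traj.frames[f], (80, 80))
            ev = attention_tick(a, o, u, params, sched, rng)
            if ev.kind != "dropped":
                assert o.count_at(ev.new_cell) > 0

    def test_attention_count_conserved_or_decreasing(self):
        rng = np.random.default_rng(6)
        env = EnvironmentConfig(
            dynamics_kind="ou", sigma=6.0, arena=(60.0, 60.0),
            updates_per_second=10.0, n_updates=40, n_targets=4, n_objects=8)
        traj = simulate_trajectory(env, seed=9)
        from mottrack.model import rasterize as rast
        a = AttentionMap(
            [(int(traj.frames[0][j, 1]), int(traj.frames[0][j, 0]))
             for j in traj.target_mask], (60, 60))
        params = ModelParams(f_loc=10.0, nob=6.0)
        sched = RoundRobinState()
        sizes = [len(a)]
        for f in range(traj.n_frames):
            if len(a) == 0:
                break
            o = rast(traj.frames[f], (60, 60))
            attention_tick(a, o, UnitaryBuffer(), params, sched, rng)
            assert a.grid.sum() == len(a)  # conservation
            sizes.append(len(a))
        assert all(b <= a_ for a_, b in zip(sizes, sizes[1:]))


class TestResolveClaims:
    def test_greedy_by_ascending_distance(self):
        claims = resolve_claims({0: (0, 0), 1: (0, 10)},
                                [(0, 1), (0, 9), (0, 20)])
        assert dict(claims) == {0: 0, 1: 1}

    def test_each_object_claimed_once(self):
        claims = resolve_claims({0: (5, 5), 1: (5, 6)}, [(5, 5), (30, 30)])
        objs = [obj for _, obj in claims]
        assert sorted(objs) == [0, 1]


class TestRunModel:
    def test_static_trial_perfect_for_any_capacity_fit(self, small_ou_env):
        import dataclasses
        env = dataclasses.replace(small_ou_env, sigma=0.0, n_targets=4,
                                  n_objects=6)
        traj = simulate_trajectory(env, seed=2)
        result = run_model_on_trajectory(
            traj, ModelParams(f_loc=20.0, nob=10.0), seed=3)
        assert result.tracking_accuracy == 1.0
        assert result.id_accuracy == 1.0

    def test_capacity_below_targets_rejected(self, small_ou_env):
        traj = simulate_trajectory(small_ou_env, seed=2)
        with pytest.raises(ValueError):
            run_model_on_trajectory(
                traj, ModelParams(f_loc=20.0, capacity=1), seed=3)

    def test_deterministic_given_seed(self, small_ou_env):
        traj = simulate_trajectory(small_ou_env, seed=2)
        params = ModelParams(f_loc=20.0, nob=30.0, f_corr=0.5,
                             scheduler="crowding_priority", c_e=2.0)
        r1 = run_model_on_trajectory(traj, params, seed=42)
        r2 = run_model_on_trajectory(traj, params, seed=42)
        assert (r1.k, r1.p, r1.claims) == (r2.k, r2.p, r2.claims)

    def test_fcorr_one_matches_tracking_on_separated_display(self):
        """With correspondence updates at every location update, identity
        accuracy equals tracking accuracy trial by trial on displays that
        keep objects apart."""
        env = EnvironmentConfig(
            dynamics_kind="constant_speed", sigma=2.0, arena=(720.0, 720.0),
            updates_per_second=60.0, n_updates=300, min_distance=80.0,
            n_targets=4, n_objects=8)
        params = ModelParams(f_loc=30.0, f_u=3.0, nob=24.0, f_corr=1.0)
        for seed in range(8):
            traj = simulate_trajectory(env, seed=seed)
            r = run_model_on_trajectory(traj, params, seed=seed)
            assert r.p == r.k

    def test_both_schedulers_run(self, small_ou_env):
        traj = simulate_trajectory(small_ou_env, seed=4)
        for sched in ("round_robin", "crowding_priority"):
            params = ModelParams(f_loc=20.0, nob=30.0, scheduler=sched,
                                 c_e=1.0)
            r = run_model_on_trajectory(traj, params, seed=5)
            assert 0.0 <= r.tracking_accuracy <= 1.0
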