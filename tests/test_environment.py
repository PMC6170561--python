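"""Leader protocol, world kinematics and the closed trial loop."""

import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from glancecf.environment import (LeaderProfile, SceneState, SimulationConfig,
                                  generate_leader_profile, leader_speed_step,
                                  run_trial, step_scene)
from glancecf.params import KMH, DriverParams


class TestGenerateLeaderProfile:
    def test_vr_targets_are_balanced_multiset(self, rng):
        prof = generate_leader_profile("vr", rng)
        counts = Counter(np.round(prof.targets / KMH).astype(int).tolist())
        assert counts == {20: 3, 40: 3, 60: 3}

    def test_vr_intervals_in_bounds(self):
        for seed in range(10):
            prof = generate_leader_profile("vr", np.random.default_rng(seed))
            st = prof.switch_times
            gaps = np.diff(np.append(st, prof.duration))
            assert np.all(gaps >= 20.0 - 1e-9) and np.all(gaps <= 30.0 + 1e-9)
            assert st[0] == 0.0

    def test_real_car_duration_and_switches(self, rng):
        prof = generate_leader_profile("real_car", rng)
        assert prof.duration == 300.0
        assert prof.switch_times[0] == 0.0
        assert np.all(prof.switch_times < 300.0)
        gaps = np.diff(prof.switch_times)
        assert np.all(gaps >= 20.0) and np.all(gaps <= 30.0)

    def test_real_car_targets_equifrequent(self):
        # iid draws from three targets -> each appears ~1/3 of the time
        all_targets = []
        for seed in range(300):
            prof = generate_leader_profile("real_car",
                                           np.random.default_rng(seed))
            all_targets.extend(np.round(prof.targets / KMH).astype(int))
        counts = Counter(all_targets)
        total = sum(counts.values())
        for k in (20, 40, 60):
            assert counts[k] / total == pytest.approx(1 / 3, abs=0.03)

    def test_unknown_protocol_raises(self, rng):
        with pytest.raises(ValueError):
            generate_leader_profile("track", rng)

    def test_reproducible(self):
        p1 = generate_leader_profile("vr", np.random.default_rng(7))
        p2 = generate_leader_profile("vr", np.random.default_rng(7))
        assert p1.segments == p2.segments


class TestLeaderSpeedStep:
    def test_ramps_up_by_step(self):
        assert leader_speed_step(10.0, 16.0, 2.0, 0.1) == pytest.approx(10.2)

    def test_ramps_down_by_step(self):
        assert leader_speed_step(10.0, 4.0, 2.0, 0.1) == pytest.approx(9.8)

    def test_snaps_to_target_without_overshoot(self):
        assert leader_speed_step(10.0, 10.1, 2.0, 0.1) == 10.1
        assert leader_speed_step(10.0, 10.0, 2.0, 0.1) == 10.0

    def test_loop_reaches_target_in_expected_time(self):
        # from 20 to 60 km/h at 2 m/s^2: (40/3.6)/2 = 5.56 s -> 56 steps
        v = 20.0 * KMH
        target = 60.0 * KMH
        steps = 0
        while v != target:
            v = leader_speed_step(v, target, 2.0, 0.1)
            steps += 1
        assert steps == math.ceil((target - 20.0 * KMH) / (2.0 * 0.1))

    def test_bad_arguments_raise(self):
        with pytest.raises(ValueError):
            leader_speed_step(10.0, 12.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            leader_speed_step(10.0, 12.0, -1.0, 0.1)


class TestStepScene:
    def test_equilibrium_is_fixed_point(self):
        s = SceneState(t=0.0, v=10.0, d=30.0, r=0.0, vL=10.0)
        s2 = step_scene(s, 0.0, 0.0, 0.1)
        assert (s2.v, s2.d, s2.r, s2.vL) == (10.0, 30.0, 0.0, 10.0)
        assert s2.t == pytest.approx(0.1)

    def test_matches_closed_form_constant_accelerations(self):
        # follower a = 1, leader aL = -0.5 from (v=10, vL=12, d=30):
        # after n steps (forward Euler, gap uses pre-step r):
        # v_n = 10 + n dt, vL_n = 12 - 0.5 n dt,
        # d_n = 30 + sum_{j<n} r_j dt with r_j = 2 - 1.5 j dt
        dt = 0.1
        s = SceneState(t=0.0, v=10.0, d=30.0, r=2.0, vL=12.0)
        for _ in range(50):
            s = step_scene(s, 1.0, -0.5, dt)
        n = 50
        assert s.v == pytest.approx(10.0 + n * dt, rel=1e-12)
        assert s.vL == pytest.approx(12.0 - 0.5 * n * dt, rel=1e-12)
        d_expected = 30.0 + sum((2.0 - 1.5 * j * dt) * dt for j in range(n))
        assert s.d == pytest.approx(d_expected, rel=1e-12)

    def test_speed_clamped_at_zero(self):
        s = SceneState(t=0.0, v=0.1, d=30.0, r=0.0, vL=0.1)
        s2 = step_scene(s, -5.0, -5.0, 0.1)
        assert s2.v == 0.0 and s2.vL == 0.0

    def test_bad_dt_raises(self):
        s = SceneState(t=0.0, v=10.0, d=30.0, r=0.0, vL=10.0)
        with pytest.raises(ValueError):
            step_scene(s, 0.0, 0.0, -0.1)


class TestRunTrial:
    def test_deterministic_given_seed(self, driver_params, short_profile,
                                      sim_config):
        r1 = run_trial(driver_params, short_profile, sim_config, seed=5)
        r2 = run_trial(driver_params, short_profile, sim_config, seed=5)
        np.testing.assert_array_equal(r1.v, r2.v)
        np.testing.assert_array_equal(r1.sigma_a, r2.sigma_a)
        np.testing.assert_array_equal(r1.lift, r2.lift)

    def test_seeds_differ(self, driver_params, short_profile, sim_config):
        r1 = run_trial(driver_params, short_profile, sim_config, seed=5)
        r2 = run_trial(driver_params, short_profile, sim_config, seed=6)
        assert not np.array_equal(r1.v, r2.v)

    def test_engines_agree(self, driver_params, short_profile):
        fast = run_trial(driver_params, short_profile,
                         SimulationConfig(engine="fast"), seed=3)
        ref = run_trial(driver_params, short_profile,
                        SimulationConfig(engine="reference"), seed=3)
        assert len(fast) == len(ref)
        np.testing.assert_allclose(fast.v, ref.v, atol=1e-9)
        np.testing.assert_allclose(fast.d, ref.d, atol=1e-9)
        np.testing.assert_allclose(fast.a, ref.a, atol=1e-9)
        np.testing.assert_allclose(fast.sigma_a, ref.sigma_a, atol=1e-5)
        np.testing.assert_array_equal(fast.occluded, ref.occluded)
        np.testing.assert_array_equal(fast.lift, ref.lift)

    def test_speed_is_integral_of_acceleration(self, driver_params,
                                               short_profile, sim_config):
        rec = run_trial(driver_params, short_profile, sim_config, seed=9)
        # v never hits the clamp in this benign scenario, so forward Euler
        # must hold exactly: v[j+1] = v[j] + a[j] dt
        assert rec.v.min() > 0
        np.testing.assert_allclose(rec.v[1:], rec.v[:-1] + rec.a[:-1] * rec.dt,
                                   atol=1e-9)

    def test_gap_is_integral_of_relative_speed(self, driver_params,
                                               short_profile, sim_config):
        rec = run_trial(driver_params, short_profile, sim_config, seed=9)
        np.testing.assert_allclose(rec.d[1:], rec.d[:-1] + rec.r[:-1] * rec.dt,
                                   atol=1e-9)

    def test_infinite_threshold_means_no_glances(self, short_profile,
                                                 sim_config):
        params = DriverParams.with_calibrated(T=1.5, a_max=1.5,
                                              sigma_a_star=np.inf)
        rec = run_trial(params, short_profile, sim_config, seed=2)
        assert rec.lift.sum() == 0
        assert np.all(rec.occluded == 1)

    def test_zero_threshold_glance_rate_is_continuous(self, short_profile,
                                                      sim_config):
        # threshold ~0: a new glance starts the moment the last one ends,
        # i.e. every n_glance-th step, and the view is never occluded
        params = DriverParams.with_calibrated(T=1.5, a_max=1.5,
                                              sigma_a_star=1e-12)
        rec = run_trial(params, short_profile, sim_config, seed=2)
        lifts = np.flatnonzero(rec.lift)
        assert np.all(np.diff(lifts) == 3)
        assert rec.occluded[lifts[0]:lifts[-1]].sum() == 0

    def test_collision_iff_final_gap_nonpositive(self, short_profile,
                                                 sim_config):
        params = DriverParams.with_calibrated(T=1.5, a_max=1.5,
                                              sigma_a_star=1.0)
        rec = run_trial(params, short_profile, sim_config, seed=9)
        if rec.outcome == "collision":
            assert rec.d[-1] <= 0
        else:
            assert np.all(rec.d > 0)

    def test_collision_truncates_record(self, sim_config):
        # an aggressive, never-looking driver starting fast into a slow
        # leader must collide and stop the record early
        profile = LeaderProfile(segments=((0.0, 20.0 * KMH),),
                                ramp_accel=2.0, protocol="real_car",
                                duration=120.0)
        params = DriverParams.with_calibrated(T=0.2, a_max=6.0,
                                              sigma_a_star=np.inf)
        cfg = replace(sim_config, v0=60.0 * KMH, gap0=8.0)
        rec = run_trial(params, profile, cfg, seed=1)
        assert rec.outcome == "collision"
        assert rec.d[-1] <= 0
        assert len(rec) < int(120.0 / rec.dt)

    def test_record_length_and_time_axis(self, driver_params, short_profile,
                                         sim_config):
        rec = run_trial(driver_params, short_profile, sim_config, seed=4)
        assert len(rec) == int(round(short_profile.duration / rec.dt))
        np.testing.assert_allclose(rec.t, np.arange(len(rec)) * rec.dt)

    def test_glance_windows_exactly_three_steps(self, driver_params,
                                                vr_profile, sim_config):
        rec = run_trial(driver_params, vr_profile, sim_config, seed=11)
        lifts = np.flatnonzero(rec.lift)
        assert lifts.size >= 5
        for i in lifts:
            assert np.all(rec.occluded[i:i + 3] == 0)
            if i + 3 < len(rec) and not np.any(rec.lift[i + 1:i + 4]):
                assert rec.occluded[i + 3] == 1
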