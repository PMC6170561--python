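"""Ground-truth world and the closed perception-action trial loop.

The environment is an infinite straight road with a leading vehicle that
follows a randomized piecewise speed protocol (targets drawn from a small
set every 20-30 s, reached with constant-magnitude ramps).  The follower
is the cognitive driver model: each 0.1 s step it (1) propagates its
particle belief with the efference copy of the previous acceleration
command, (2) receives a noisy percept given the occlusion state,
(3) reweights and systematically resamples the particles, (4) maps the
belief through the IDM to an acceleration distribution, (5) makes the
uncertainty-triggered glance decision, and (6) actuates the mean
acceleration, which the environment integrates exactly (no actuation
noise).  A trial ends when the protocol ends or the bumper-to-bumper gap
reaches zero (collision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import control as ctrl
from . import perception as perc
from . import state_estimator as se
from .params import KMH, DriverParams

__all__ = [
    "SceneState",
    "LeaderProfile",
    "SimulationConfig",
    "TrialRecord",
    "generate_leader_profile",
    "leader_speed_step",
    "step_scene",
    "run_trial",
]

#: Leader target-speed set of the experiment protocol, km/h.
DEFAULT_TARGETS_KMH = (20.0, 40.0, 60.0)
#: Bounds of the uniform inter-switch interval, s.
DEFAULT_SWITCH_INTERVAL = (20.0, 30.0)
#: Leader ramp magnitude toward the target speed, m/s^2.
DEFAULT_RAMP = 2.0
#: Fixed real-car trial duration, s.
REAL_CAR_DURATION = 300.0


@dataclass(frozen=True)
class SceneState:
    """Ground-truth kinematic state at one instant."""

    t: float           #: time, s
    v: float           #: follower speed, m/s
    d: float           #: bumper-to-bumper gap, m
    r: float           #: relative speed, leader minus follower, m/s
    vL: float          #: leader speed, m/s
    a_actuated: float = 0.0  #: current follower acceleration, m/s^2


@dataclass(frozen=True)
class LeaderProfile:
    """Piecewise-constant-target leader speed protocol.

    ``segments`` is an ordered list of ``(switch_time, target_speed)``
    pairs (s, m/s); the leader ramps toward the active target at
    ``ramp_accel``.  ``duration`` is the trial length in seconds.
    """

    segments: tuple
    ramp_accel: float
    protocol: str
    duration: float

    @property
    def switch_times(self) -> np.ndarray:
        return np.array([s[0] for s in self.segments])

    @property
    def targets(self) -> np.ndarray:
        return np.array([s[1] for s in self.segments])


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation-side knobs (world clock, filter size, initial state)."""

    dt: float = 0.1            #: timestep for world and filter, s
    n_particles: int = 512     #: particle count
    v0: float | None = None    #: initial follower speed; None = first target
    gap0: float = 30.0         #: initial bumper-to-bumper gap, m
    r0: float = 0.0            #: initial relative speed, m/s
    init_d_range: tuple = se.INIT_D_RANGE
    init_r_range: tuple = se.INIT_R_RANGE
    leader_speed_prior: bool = True
    engine: str = "fast"       #: "fast" (numba kernel) or "reference"


@dataclass
class TrialRecord:
    """Full time series of one simulated trial.

    All arrays are aligned per step.  ``occluded`` is the recorded
    occlusion flag (0 during a glance window), ``lift`` marks the steps at
    which the driver pressed for a glance.
    """

    t: np.ndarray
    v: np.ndarray
    vL: np.ndarray
    d: np.ndarray
    r: np.ndarray
    a: np.ndarray          #: actuated acceleration, m/s^2
    sigma_a: np.ndarray    #: acceleration-distribution s.d., m/s^2
    occluded: np.ndarray   #: int8 flag
    lift: np.ndarray       #: int8 flag
    outcome: str           #: "completed" or "collision"
    seed: int | None
    dt: float
    t_G: float
    params: dict = field(default_factory=dict)

    @property
    def lift_times(self) -> np.ndarray:
        return self.t[self.lift.astype(bool)]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)

    def __len__(self) -> int:
        return self.t.size


def generate_leader_profile(protocol: str, rng: np.random.Generator,
                            targets_kmh: Sequence[float] = DEFAULT_TARGETS_KMH,
                            switch_interval=DEFAULT_SWITCH_INTERVAL,
                            ramp_accel: float = DEFAULT_RAMP,
                            duration: float = REAL_CAR_DURATION,
                            ) -> LeaderProfile:
    """Draw a randomized leader speed protocol.

    ``real_car``: targets drawn independently and uniformly from the
    target set, segments covering the fixed trial ``duration`` (300 s by
    default).  ``vr``: exactly nine segments, each target appearing
    exactly three times in uniformly random order; the trial ends when the
    last segment completes.  Inter-switch intervals are uniform on
    ``switch_interval`` in both protocols; the first target is active
    from t = 0.
    """
    targets = np.asarray(targets_kmh, dtype=float) * KMH
    if targets.size == 0:
        raise ValueError("target set must be non-empty")
    lo, hi = switch_interval
    if protocol == "real_car":
        times = [0.0]
        while times[-1] < duration:
            times.append(times[-1] + rng.uniform(lo, hi))
        times = times[:-1] if times[-1] >= duration else times
        # the loop exits with the last switch beyond the duration; drop it
        tg = targets[rng.integers(0, targets.size, size=len(times))]
        segs = tuple(zip(times, tg))
        return LeaderProfile(segs, ramp_accel, "real_car", float(duration))
    if protocol == "vr":
        order = rng.permutation(np.repeat(targets, 3))
        intervals = rng.uniform(lo, hi, size=order.size)
        times = np.concatenate(([0.0], np.cumsum(intervals)[:-1]))
        segs = tuple(zip(times.tolist(), order.tolist()))
        return LeaderProfile(segs, ramp_accel, "vr",
                             float(np.sum(intervals)))
    raise ValueError(f"unknown protocol {protocol!r}; use 'real_car' or 'vr'")


def leader_speed_step(vL: float, target: float, ramp: float,
                      dt: float) -> float:
    """Advance the leader speed one step toward the target.

    Moves by at most ``ramp * dt`` and snaps to the target without
    overshoot.
    """
    if dt <= 0 or ramp <= 0:
        raise ValueError("dt and ramp must be > 0")
    delta = target - vL
    step = ramp * dt
    if abs(delta) <= step:
        return float(target)
    return float(vL + math.copysign(step, delta))


def step_scene(scene: SceneState, a_follower: float, aL: float,
               dt: float) -> SceneState:
    """Forward-Euler kinematics, exact actuation, speeds clamped at 0.

    The gap integrates the pre-step relative speed; a post-step gap of
    zero or less signals a collision to the caller.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v_new = max(0.0, scene.v + a_follower * dt)
    vL_new = max(0.0, scene.vL + aL * dt)
    d_new = scene.d + scene.r * dt
    return SceneState(t=scene.t + dt, v=v_new, d=d_new,
                      r=vL_new - v_new, vL=vL_new, a_actuated=a_follower)


class TrialNumericsError(RuntimeError):
    """Non-finite state encountered during a trial."""


def _record_from_arrays(arrays, n_rec, collided, seed, dt, t_G,
                        params_dict) -> TrialRecord:
    t, v, vL, d, r, a, sig, occ, lift = (x[:n_rec] for x in arrays)
    return TrialRecord(
        t=t.copy(), v=v.copy(), vL=vL.copy(), d=d.copy(), r=r.copy(),
        a=a.copy(), sigma_a=sig.copy(), occluded=occ.copy(),
        lift=lift.copy(),
        outcome="collision" if collided else "completed",
        seed=seed, dt=dt, t_G=t_G, params=params_dict)


def run_trial(params: DriverParams, profile: LeaderProfile,
              config: SimulationConfig | None = None,
              seed: int | None = None) -> TrialRecord:
    """Run one closed-loop trial; fully reproducible from its arguments.

    A single seeded generator supplies every source of randomness; within
    a step the draws occur in a fixed order (own-acceleration noise,
    leader-acceleration noise, the three percept noises, the resampling
    offset), so identical ``(params, profile, config, seed)`` give a
    bit-identical record.
    """
    config = config or SimulationConfig()
    params.validate()
    rng = np.random.default_rng(seed)
    dt = config.dt
    n_steps = int(round(profile.duration / dt))
    n_glance = max(1, int(round(params.attention.t_G / dt)))
    v0 = config.v0 if config.v0 is not None else float(profile.targets[0])

    args = (
        rng, n_steps, dt, config.n_particles,
        float(v0), float(config.gap0), float(config.r0),
        profile.switch_times.astype(float), profile.targets.astype(float),
        float(profile.ramp_accel),
        params.perception.sigma_F, params.perception.sigma_phi,
        params.perception.sigma_vphi, params.perception.u,
        params.perception.d0, params.perception.v_floor,
        params.prediction.lambda_a, params.prediction.sigma_aL,
        params.idm.v_max, params.idm.T, params.idm.a_max, params.idm.b_max,
        params.idm.delta, params.idm.s0, params.idm.s1,
        params.attention.sigma_a_star, n_glance,
        float(config.init_d_range[0]), float(config.init_d_range[1]),
        float(config.init_r_range[0]), float(config.init_r_range[1]),
        config.leader_speed_prior,
    )
    if config.engine == "fast":
        from ._kernel import run_trial_kernel
        status, err_step, n_rec, collided, *arrays = run_trial_kernel(*args)
    elif config.engine == "reference":
        status, err_step, n_rec, collided, *arrays = _run_trial_reference(*args)
    else:
        raise ValueError(f"unknown engine {config.engine!r}")

    if status == 1:
        raise se.DegeneratePosteriorError(
            f"all particle weights vanished at step {err_step}")
    if status == 2:
        raise TrialNumericsError(f"non-finite state at step {err_step}")

    pdict = {
        "T": params.idm.T, "a_max": params.idm.a_max,
        "sigma_a_star": params.attention.sigma_a_star,
        "protocol": profile.protocol, "n_particles": config.n_particles,
        "dt": dt, "engine": config.engine,
    }
    return _record_from_arrays(arrays, n_rec, collided, seed, dt,
                               n_glance * dt, pdict)


def _run_trial_reference(rng, n_steps, dt, n_particles,
                         v0, gap0, r0,
                         switch_times, targets, ramp,
                         sigma_F, sigma_phi, sigma_vphi, u_w, d_front,
                         v_floor, lam_a, sigma_aL,
                         v_max, T, a_max, b_max, delta, s0, s1,
                         sigma_star, n_glance,
                         d_lo, d_hi, r_lo, r_hi, leader_speed_prior):
    """Trial loop composed from the public per-operation functions.

    Consumes the random stream in the same order as the compiled kernel;
    used to cross-check the kernel on short trials.
    """
    from dataclasses import replace

    from .params import (AttentionParams, IDMParams, PerceptionParams,
                         PredictionParams)

    pparams = PerceptionParams(sigma_F=sigma_F, sigma_phi=sigma_phi,
                               sigma_vphi=sigma_vphi, u=u_w, d0=d_front,
                               v_floor=v_floor)
    predp = PredictionParams(lambda_a=lam_a, sigma_aL=sigma_aL, dt=dt)
    idmp = IDMParams(v_max=v_max, T=T, a_max=a_max, b_max=b_max,
                     delta=delta, s0=s0, s1=s1)

    belief = se.init_belief(v0, n_particles, rng, d_range=(d_lo, d_hi),
                            r_range=(r_lo, r_hi),
                            leader_speed_prior=leader_speed_prior)
    scene = SceneState(t=0.0, v=v0, d=gap0, r=r0, vL=v0 + r0)

    out = [np.zeros(n_steps + 1) for _ in range(7)]
    occ_arr = np.zeros(n_steps + 1, dtype=np.int8)
    lift_arr = np.zeros(n_steps + 1, dtype=np.int8)
    t_a, v_a, vL_a, d_a, r_a, a_a, s_a = out

    a_prev = 0.0
    glance_start = -(2 ** 30)
    seg = 0
    n_rec = 0
    collided = False
    for j in range(n_steps):
        t = j * dt
        while seg + 1 < len(switch_times) and switch_times[seg + 1] <= t + 1e-9:
            seg += 1
        belief = se.predict_step(belief, a_prev, predp, rng)
        visible = (j > glance_start) and (j - glance_start < n_glance)
        percept = perc.sample_percept(scene, False, pparams, rng)
        if not visible:
            percept = replace(percept, leader_visible=False)
        belief = se.update_step(belief, percept, not visible, pparams)
        belief = se.systematic_resample(belief, rng)
        cout = ctrl.acceleration_distribution(belief, idmp)
        occluded_now = (j - glance_start) >= n_glance
        lift = occluded_now and (cout.sigma_a > sigma_star)
        if lift:
            glance_start = j
        occ = 0 if (j - glance_start) < n_glance else 1
        t_a[j], v_a[j], vL_a[j], d_a[j], r_a[j] = (t, scene.v, scene.vL,
                                                   scene.d, scene.r)
        a_a[j], s_a[j] = cout.a_bar, cout.sigma_a
        occ_arr[j], lift_arr[j] = occ, int(lift)
        n_rec = j + 1
        if not (math.isfinite(cout.a_bar) and math.isfinite(cout.sigma_a)
                and math.isfinite(scene.d)):
            return 2, j, n_rec, collided, t_a, v_a, vL_a, d_a, r_a, a_a, s_a, \
                occ_arr, lift_arr
        vL_new = leader_speed_step(scene.vL, targets[seg], ramp, dt)
        aL = (vL_new - scene.vL) / dt
        scene = step_scene(scene, cout.a_bar, aL, dt)
        a_prev = cout.a_bar
        if scene.d <= 0:
            collided = True
            jj = j + 1
            t_a[jj], v_a[jj], vL_a[jj] = scene.t, scene.v, scene.vL
            d_a[jj], r_a[jj] = scene.d, scene.r
            a_a[jj], s_a[jj] = cout.a_bar, cout.sigma_a
            occ_arr[jj] = 0 if (jj - glance_start) < n_glance else 1
            n_rec = jj + 1
            break
    return 0, -1, n_rec, collided, t_a, v_a, vL_a, d_a, r_a, a_a, s_a, \
        occ_arr, lift_arr
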