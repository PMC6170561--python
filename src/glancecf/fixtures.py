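"""Reproducible synthetic fixtures.

Everything the analysis and calibration machinery consumes can be
generated deterministically from a seed: leader profiles, full synthetic
trials, a mini virtual dataset and a hand-built toy record with known
glance times.  No downloads, no binary data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import simulate_virtual_dataset
from .environment import (SimulationConfig, TrialRecord,
                          generate_leader_profile, run_trial)
from .io import write_trajectory_csv
from .params import DriverParams

__all__ = ["toy_three_lift_record", "make_fixture_suite"]

#: Driver parameters used for the shipped synthetic trials: a mid-range,
#: non-crashing parametrization (T = 1.5 s, a_max = 1.5 m/s^2,
#: sigma_a_star = 1.0 m/s^2).
FIXTURE_DRIVER = DriverParams.with_calibrated(T=1.5, a_max=1.5,
                                              sigma_a_star=1.0)


def toy_three_lift_record(lift_times=(1.0, 2.0, 4.0), duration: float = 6.0,
                          v: float = 10.0, d: float = 20.0,
                          dt: float = 0.1, t_G: float = 0.3) -> TrialRecord:
    """Hand-built constant-state record with known glance times.

    With the default lifts at (1.0, 2.0, 4.0) s and a 0.3 s glance the
    expected occlusion durations are (0.7, 1.7) s.
    """
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    lift = np.zeros(n, dtype=np.int8)
    occ = np.ones(n, dtype=np.int8)
    n_g = int(round(t_G / dt))
    for lt in lift_times:
        i = int(round(lt / dt))
        lift[i] = 1
        occ[i:i + n_g] = 0
    return TrialRecord(
        t=t, v=np.full(n, v), vL=np.full(n, v), d=np.full(n, d),
        r=np.zeros(n), a=np.zeros(n), sigma_a=np.zeros(n),
        occluded=occ, lift=lift, outcome="completed", seed=None,
        dt=dt, t_G=t_G)


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write the deterministic fixture suite under ``out_dir``.

    Produces three leader profiles, five synthetic trial CSVs, a 200-row
    mini virtual dataset (reduced to 64 particles to keep generation
    quick) and the toy three-lift record with its expected occlusion
    durations.  Byte-identical for equal seeds.  Returns the mapping of
    fixture names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    rng = np.random.default_rng(seed)
    for i, protocol in enumerate(["real_car", "vr", "vr"]):
        prof = generate_leader_profile(protocol, rng)
        df = pd.DataFrame(list(prof.segments),
                          columns=["switch_time", "target_speed"])
        p = out / f"leader_profile_{i}_{protocol}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        written[f"leader_profile_{i}"] = p

    cfg = SimulationConfig()
    for i in range(5):
        s = seed * 1000 + i
        prof = generate_leader_profile("vr", np.random.default_rng(s))
        rec = run_trial(FIXTURE_DRIVER, prof, cfg, seed=s)
        p = out / f"trial_{i}.csv"
        write_trajectory_csv(rec, p)
        written[f"trial_{i}"] = p

    mini = simulate_virtual_dataset(
        200, base_seed=seed,
        config=SimulationConfig(n_particles=64))
    p = out / "mini_virtual_dataset.csv"
    mini.table.to_csv(p, index=False, float_format="%.12g")
    written["mini_virtual_dataset"] = p

    toy = toy_three_lift_record()
    p = out / "toy_three_lift.csv"
    write_trajectory_csv(toy, p)
    written["toy_three_lift"] = p
    meta = {"lift_times": [1.0, 2.0, 4.0],
            "expected_occlusion_durations": [0.7, 1.7], "t_G": 0.3}
    p = out / "toy_three_lift_expected.json"
    p.write_text(json.dumps(meta, indent=2))
    written["toy_three_lift_expected"] = p
    return written
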