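"""Simulation-based calibration of the three driver-specific parameters.

Estimating car-following parameters from trajectories directly is plagued
by local minima and overfitting, so calibration proceeds by simulation:
a *virtual dataset* of trials is generated with the three free parameters
(desired time headway ``T``, maximum acceleration ``a_max``, uncertainty
threshold ``sigma_a_star``) drawn from broad uniform priors, each trial is
summarized by three aggregate features (median time headway, median
occlusion duration, 99th percentile of acceleration), and a subject's
parameters are estimated as the mean of the parameters that generated the
``k`` virtual trials closest to the subject's features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis
from .environment import (SimulationConfig, TrialRecord,
                          generate_leader_profile, run_trial)
from .params import DriverParams

__all__ = [
    "PRIOR_RANGES",
    "TrialFeatures",
    "VirtualDataset",
    "trial_features",
    "aggregate_features",
    "simulate_virtual_dataset",
    "knn_calibrate",
]

#: Uniform prior boxes for (T [s], a_max [m/s^2], sigma_a_star [m/s^2]).
PRIOR_RANGES = {
    "T": (0.1, 15.0),
    "a_max": (0.1, 8.0),
    "sigma_a_star": (0.1, 8.0),
}

FEATURE_COLUMNS = ("median_thw", "median_occl", "p99_accel")
PARAM_COLUMNS = ("T", "a_max", "sigma_a_star")


@dataclass(frozen=True)
class TrialFeatures:
    """Aggregate behavioural features of one trial (or one subject)."""

    median_thw: float    #: median time headway d/v, s
    median_occl: float   #: median occlusion duration, s
    p99_accel: float     #: 99th percentile of actuated acceleration, m/s^2

    def as_array(self) -> np.ndarray:
        return np.array([self.median_thw, self.median_occl, self.p99_accel])


@dataclass
class VirtualDataset:
    """Rows of (parameters, features) from randomly parametrized trials."""

    table: pd.DataFrame
    priors: dict
    protocol: str

    def __len__(self) -> int:
        return len(self.table)


def trial_features(record: TrialRecord, v_floor: float = 0.1) -> TrialFeatures:
    """Summarize one trial by the three calibration features.

    Headway uses ``d / v`` with near-standstill steps (``v < v_floor``)
    excluded.  The occlusion-duration series needs at least two glances;
    with fewer the trial-long occlusion is censored at the trial duration.
    The acceleration percentile is of the signed actuated acceleration.
    """
    moving = record.v >= v_floor
    thw = record.d[moving] / record.v[moving]
    median_thw = float(np.median(thw)) if thw.size else float("nan")
    series = analysis.occlusion_durations(record.lift_times, record.t_G)
    if series.durations.size:
        median_occl = float(np.median(series.durations))
    else:
        median_occl = record.duration
    p99 = float(np.percentile(record.a, 99.0))
    return TrialFeatures(median_thw, median_occl, p99)


def aggregate_features(per_trial: list[TrialFeatures]) -> TrialFeatures:
    """Subject-level features: the median of per-trial features."""
    arr = np.array([f.as_array() for f in per_trial])
    med = np.median(arr, axis=0)
    return TrialFeatures(*med)


def simulate_virtual_dataset(n_trials: int,
                             priors: dict | None = None,
                             protocol: str = "vr",
                             base_seed: int | None = None,
                             base_params: DriverParams | None = None,
                             config: SimulationConfig | None = None,
                             ) -> VirtualDataset:
    """Simulate the virtual dataset for k-NN calibration.

    Each row is one trial with an independent draw of the three free
    parameters from ``priors`` and its own trial seed and leader profile;
    everything is reproducible from ``base_seed``.  Crashed trials are
    kept, flagged, with features computed over the steps before the crash.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    priors = priors or PRIOR_RANGES
    config = config or SimulationConfig()
    base_params = base_params or DriverParams()
    root = np.random.default_rng(base_seed)
    rows = []
    for _ in range(n_trials):
        T = root.uniform(*priors["T"])
        a_max = root.uniform(*priors["a_max"])
        s_star = root.uniform(*priors["sigma_a_star"])
        seed = int(root.integers(0, 2 ** 31 - 1))
        params = DriverParams.with_calibrated(
            T, a_max, s_star,
            perception=base_params.perception,
            prediction=base_params.prediction)
        profile = generate_leader_profile(
            protocol, np.random.default_rng(seed))
        rec = run_trial(params, profile, config, seed=seed)
        feats = trial_features(rec)
        rows.append((T, a_max, s_star, feats.median_thw, feats.median_occl,
                     feats.p99_accel, rec.outcome == "collision", seed))
    table = pd.DataFrame(rows, columns=list(PARAM_COLUMNS)
                         + list(FEATURE_COLUMNS) + ["crashed", "seed"])
    return VirtualDataset(table=table, priors=dict(priors), protocol=protocol)


def knn_calibrate(subject: TrialFeatures, dataset: VirtualDataset,
                  k: int = 5) -> tuple[float, float, float]:
    """Estimate (T, a_max, sigma_a_star) by k-NN in feature space.

    Features are z-scored by the virtual dataset's mean and standard
    deviation (the three features have incommensurate units), distance is
    Euclidean, and the estimate is the unweighted mean of the parameters
    of the ``k`` nearest rows.  Ties are broken by dataset row order.
    """
    table = dataset.table
    if k < 1 or k > len(table):
        raise ValueError(f"k={k} must be in [1, {len(table)}]")
    feats = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    q = (subject.as_array() - mu) / sd
    dist = np.sqrt(((z - q) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    est = table.iloc[order][list(PARAM_COLUMNS)].mean(axis=0)
    return float(est["T"]), float(est["a_max"]), float(est["sigma_a_star"])
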