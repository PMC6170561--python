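"""Behavioural statistics of occluded car following.

Implements the occlusion-paradigm measures: occlusion durations between
self-paced glances, the pairing of time headway at a glance with the
duration of the occlusion that follows it, robust (Theil-Sen) per-trial
detrending, within-subject Spearman rank correlations, an exact sign
(binomial) test over subjects, and Monte-Carlo crash rates with exact
binomial confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .environment import SimulationConfig, TrialRecord, generate_leader_profile, run_trial
from .params import DriverParams

logger = logging.getLogger(__name__)

__all__ = [
    "OcclusionSeries",
    "occlusion_durations",
    "pair_headway_occlusion",
    "detrend_robust",
    "within_subject_correlation",
    "subject_spearman",
    "sign_binomial_test",
    "crash_rate",
]


@dataclass(frozen=True)
class OcclusionSeries:
    """Occlusion durations following each glance (the last glance has none)."""

    glance_times: np.ndarray  #: s
    durations: np.ndarray     #: s


def occlusion_durations(lift_times, t_G: float) -> OcclusionSeries:
    """Occluded interval after each glance.

    The interval between successive glance requests minus the unoccluded
    glance window ``t_G``, floored at zero.  Fewer than two lifts give an
    empty series.
    """
    lt = np.asarray(lift_times, dtype=float)
    if lt.size >= 2 and np.any(np.diff(lt) <= 0):
        raise ValueError("lift times must be strictly increasing")
    if lt.size < 2:
        return OcclusionSeries(np.empty(0), np.empty(0))
    dur = np.maximum(np.diff(lt) - t_G, 0.0)
    return OcclusionSeries(lt[:-1].copy(), dur)


def pair_headway_occlusion(record: TrialRecord, v_floor: float = 0.1):
    """Pair the headway at each glance with the following occlusion duration.

    Returns ``(times, thw, durations)`` arrays over all glances except the
    last.  Headway is sampled at the glance step; pairs where the follower
    is near standstill (``v < v_floor``) are dropped to avoid division
    blow-up.
    """
    idx = np.flatnonzero(record.lift.astype(bool))
    if idx.size < 2:
        return np.empty(0), np.empty(0), np.empty(0)
    series = occlusion_durations(record.t[idx], record.t_G)
    lead = idx[:-1]
    keep = record.v[lead] >= v_floor
    thw = record.d[lead[keep]] / record.v[lead[keep]]
    return record.t[lead[keep]], thw, series.durations[keep]


def detrend_robust(times, values):
    """Remove a robust linear trend (Theil-Sen slope, median intercept).

    With fewer than three points detrending is skipped and the values are
    returned unchanged (with a logged warning).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        logger.warning("detrend_robust: fewer than 3 points, passing through")
        return y.copy()
    slope, intercept, _, _ = stats.theilslopes(y, t)
    return y - (slope * t + intercept)


def within_subject_correlation(thw, durations, times=None, detrend=True):
    """Spearman rank correlation of headway vs following occlusion duration.

    With ``detrend`` the robust linear trend against ``times`` is removed
    from each margin first (to discard slow drifts in headway preference).
    Ties get average ranks.  Returns NaN when either margin has zero
    variance or there are fewer than three pairs.
    """
    thw = np.asarray(thw, dtype=float)
    dur = np.asarray(durations, dtype=float)
    if thw.size < 3:
        return float("nan")
    if detrend:
        if times is None:
            raise ValueError("detrending requires glance times")
        thw = detrend_robust(times, thw)
        dur = detrend_robust(times, dur)
    if np.ptp(thw) == 0 or np.ptp(dur) == 0:
        return float("nan")
    rho = stats.spearmanr(thw, dur).statistic
    return float(rho)


def subject_spearman(records: list[TrialRecord], detrend: bool = True) -> float:
    """Within-subject correlation pooled over trials.

    Headway-occlusion pairs are detrended per trial, then pooled across
    the subject's trials before computing the rank correlation.
    """
    thw_all, dur_all = [], []
    for rec in records:
        t, thw, dur = pair_headway_occlusion(rec)
        if thw.size < 3:
            continue
        if detrend:
            thw = detrend_robust(t, thw)
            dur = detrend_robust(t, dur)
        thw_all.append(thw)
        dur_all.append(dur)
    if not thw_all:
        return float("nan")
    thw_all = np.concatenate(thw_all)
    dur_all = np.concatenate(dur_all)
    return within_subject_correlation(thw_all, dur_all, detrend=False)


def sign_binomial_test(n_positive: int, n: int) -> float:
    """Exact two-sided sign test against proportion one half.

    Doubles the smaller binomial tail and caps at 1.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= n_positive <= n:
        raise ValueError("n_positive must be in [0, n]")
    lower = stats.binom.cdf(n_positive, n, 0.5)
    upper = stats.binom.sf(n_positive - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def crash_rate(params: DriverParams, protocol: str = "vr",
               n_trials: int = 300, seed: int | None = None,
               config: SimulationConfig | None = None):
    """Monte-Carlo crash fraction with a Clopper-Pearson 95% interval.

    Simulates ``n_trials`` independent trials (fresh leader profile and
    driver noise each) and counts collisions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or SimulationConfig()
    root = np.random.default_rng(seed)
    crashes = 0
    for _ in range(n_trials):
        s = int(root.integers(0, 2 ** 31 - 1))
        profile = generate_leader_profile(protocol, np.random.default_rng(s))
        rec = run_trial(params, profile, config, seed=s)
        crashes += rec.outcome == "collision"
    rate = crashes / n_trials
    lo = (0.0 if crashes == 0
          else float(stats.beta.ppf(0.025, crashes, n_trials - crashes + 1)))
    hi = (1.0 if crashes == n_trials
          else float(stats.beta.ppf(0.975, crashes + 1, n_trials - crashes)))
    return rate, (lo, hi)
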