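"""Acceleration choice and uncertainty-driven attention.

The control rule is the Intelligent Driver Model (IDM).  Applying it to
every particle of the belief turns the state posterior into a
*distribution of accelerations*; its weighted mean is actuated and its
weighted standard deviation is the driver's *action uncertainty*.  When
the view is occluded and the action uncertainty exceeds the driver's
threshold, the occlusion is lifted for a ``t_G`` (default 300 ms) glance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AttentionParams, IDMParams
from .state_estimator import BeliefState, belief_moments

__all__ = [
    "ControlOutput",
    "OcclusionState",
    "idm_acceleration",
    "acceleration_distribution",
    "attention_step",
]

#: Tolerance for continuous-time glance bookkeeping (guards against
#: accumulated float error in t + t_G comparisons).
_T_EPS = 1e-9


@dataclass(frozen=True)
class OcclusionState:
    """Occlusion device bookkeeping.

    ``glance_end`` is the time the view re-occludes; it is meaningless
    while ``occluded`` is true.
    """

    occluded: bool = True
    glance_end: float = -np.inf


@dataclass(frozen=True)
class ControlOutput:
    """One step of control: actuated acceleration, uncertainty, lift flag."""

    a_bar: float
    sigma_a: float
    lift: bool | None = None


def idm_acceleration(v, d, r, p: IDMParams):
    """IDM acceleration for state ``(v, d, r)``.

    ``a = a_max [1 - (v / v_max)^delta - (s*(v, dv) / d)^2]`` with the
    desired gap ``s*(v, dv) = s0 + max(0, s1 sqrt(v / v_max) + v T +
    v dv / (2 sqrt(a_max b_max)))`` and the approach rate ``dv = -r``
    (follower speed minus leader speed).  The dynamic part of ``s*`` is
    floored so that ``s* >= s0`` during hard opening.
    """
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(d <= 0):
        raise ValueError("IDM undefined for gap d <= 0")
    dv = -r
    s_dyn = (p.s1 * np.sqrt(np.maximum(v, 0.0) / p.v_max) + v * p.T
             + v * dv / (2.0 * np.sqrt(p.a_max * p.b_max)))
    s_star = p.s0 + np.maximum(s_dyn, 0.0)
    a = p.a_max * (1.0 - (v / p.v_max) ** p.delta - (s_star / d) ** 2)
    return float(a) if a.ndim == 0 else a


def acceleration_distribution(belief: BeliefState,
                              p: IDMParams) -> ControlOutput:
    """Map the belief through the IDM and take weighted moments.

    Particles with a non-positive gap contribute the strongest braking
    ``-b_max`` (they are transient and killed by the likelihood); this
    keeps the acceleration distribution defined.  No actuation noise is
    added and the mean is not clipped — the model controls acceleration
    directly and may command physically unrealistic values.
    """
    acc = np.empty(belief.n)
    ok = belief.d > 0
    if np.any(ok):
        acc[ok] = idm_acceleration(belief.v[ok], belief.d[ok], belief.r[ok], p)
    acc[~ok] = -p.b_max
    a_bar, sigma_a = belief_moments(belief, acc)
    return ControlOutput(a_bar=a_bar, sigma_a=sigma_a, lift=None)


def attention_step(sigma_a: float, occl: OcclusionState, t: float,
                   ap: AttentionParams):
    """One attention decision at time ``t``.

    The occlusion re-engages automatically once a running glance has
    lasted ``t_G``.  A lift happens only when the view is (again) occluded
    and the action uncertainty exceeds the threshold; a lift opens the
    view for ``[t, t + t_G)``.  A glance cannot re-trigger mid-glance.

    Returns ``(lift, new_state)``.
    """
    occluded = occl.occluded
    glance_end = occl.glance_end
    if not occluded and t >= glance_end - _T_EPS:
        occluded = True
    if occluded and sigma_a > ap.sigma_a_star:
        return True, OcclusionState(occluded=False, glance_end=t + ap.t_G)
    return False, OcclusionState(occluded=occluded, glance_end=glance_end)
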