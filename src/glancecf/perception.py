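"""Psychophysically motivated percept model.

The driver does not observe the scene variables (own speed ``v``, gap
``d``, relative speed ``r``) directly.  Instead three visual percepts are
available:

* optic-flow magnitude ``F = log(v)``, carrying own-speed information,
* the leading vehicle's angular width ``phi`` (degrees), carrying distance
  information, and
* the angular expansion rate ("looming") ``v_phi`` (degrees/s), carrying
  relative-speed information.

Each percept is corrupted by Gaussian noise of constant standard deviation
*in percept space*, so the implied accuracy in state space degrades with
magnitude: own-speed error grows linearly with speed and distance error
grows super-linearly with distance.  When the view is occluded only the
optic flow is available (self-motion information does not depend on seeing
the leader).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import PerceptionParams

RAD2DEG = 180.0 / math.pi

__all__ = [
    "Percept",
    "optic_flow_true",
    "angular_width_true",
    "angular_expansion_true",
    "sample_percept",
    "percept_log_likelihood",
]


@dataclass(frozen=True)
class Percept:
    """One noisy observation.

    ``phi`` and ``v_phi`` are only meaningful when ``leader_visible`` is
    true; they are stored as NaN otherwise.
    """

    F: float
    phi: float
    v_phi: float
    leader_visible: bool


def optic_flow_true(v, v_floor: float = 0.1):
    """Noise-free optic-flow magnitude ``log(max(v, v_floor))``.

    The clamp keeps the transform defined at standstill; ``v_floor`` is in
    m/s.
    """
    return np.log(np.maximum(v, v_floor))


def angular_width_true(d, params: PerceptionParams):
    """Noise-free angular width of the leader in degrees.

    ``phi*(d) = 2 atan(u / (2 (d + d0)))`` where ``u`` is the leader's
    width and ``d0`` the driver's distance to the own front bumper.
    """
    dd = np.asarray(d, dtype=float) + params.d0
    if np.any(dd <= 0):
        raise ValueError("angular width undefined for d + d0 <= 0")
    out = 2.0 * np.arctan(params.u / (2.0 * dd)) * RAD2DEG
    return float(out) if np.isscalar(d) else out


def angular_expansion_true(d, r, params: PerceptionParams):
    """Noise-free angular expansion rate in degrees/s.

    ``v_phi*(d, r) = -4 u r / (4 (d + d0)^2 + u^2)``; this is the time
    derivative of :func:`angular_width_true` along ``d' = r`` (a receding
    leader, ``r > 0``, shrinks the image, hence the negative sign).
    """
    dd = np.asarray(d, dtype=float) + params.d0
    if np.any(dd <= 0):
        raise ValueError("angular expansion undefined for d + d0 <= 0")
    out = -4.0 * params.u * np.asarray(r, dtype=float) / (
        4.0 * dd * dd + params.u * params.u) * RAD2DEG
    return float(out) if np.isscalar(d) and np.isscalar(r) else out


def sample_percept(scene, occluded: bool, params: PerceptionParams,
                   rng: np.random.Generator) -> Percept:
    """Draw one noisy percept from the true scene.

    The optic flow is always available; the leader-related percepts are
    populated only when the view is not occluded.  Noise is added in
    percept space.
    """
    F = float(optic_flow_true(scene.v, params.v_floor)
              + params.sigma_F * rng.standard_normal())
    if occluded:
        return Percept(F=F, phi=math.nan, v_phi=math.nan, leader_visible=False)
    phi = float(angular_width_true(scene.d, params)
                + params.sigma_phi * rng.standard_normal())
    v_phi = float(angular_expansion_true(scene.d, scene.r, params)
                  + params.sigma_vphi * rng.standard_normal())
    return Percept(F=F, phi=phi, v_phi=v_phi, leader_visible=True)


def _norm_logpdf(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * math.log(2.0 * math.pi)


def percept_log_likelihood(percept: Percept, particle, occluded: bool,
                           params: PerceptionParams):
    """Log observation density of a percept given a candidate state.

    ``particle`` is a triple ``(v, d, r)`` of scalars or aligned arrays.
    When the view is occluded only the optic-flow term enters, so the
    result does not depend on ``d`` or ``r``.  Physically invalid
    candidates (``v < 0`` or ``d + d0 <= 0``) get ``-inf`` so the Bayes
    update removes them without biasing valid ones.
    """
    v, d, r = (np.asarray(x, dtype=float) for x in particle)
    scalar = v.ndim == 0 and d.ndim == 0 and r.ndim == 0
    v, d, r = np.atleast_1d(*np.broadcast_arrays(v, d, r))
    valid = (v >= 0) & (d + params.d0 > 0)

    ll = np.full(v.shape, -np.inf)
    if np.any(valid):
        vv, dv, rv = v[valid], d[valid], r[valid]
        out = _norm_logpdf(percept.F, optic_flow_true(vv, params.v_floor),
                           params.sigma_F)
        if not occluded:
            out = out + _norm_logpdf(percept.phi,
                                     angular_width_true(dv, params),
                                     params.sigma_phi)
            out = out + _norm_logpdf(percept.v_phi,
                                     angular_expansion_true(dv, rv, params),
                                     params.sigma_vphi)
        ll[valid] = out
    return float(ll[0]) if scalar else ll
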