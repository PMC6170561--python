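"""Bootstrap particle filter over the driver's internal scene estimate.

The driver's belief about the scene is a weighted particle cloud over
``(v, d, r)`` — own speed, gap and relative speed.  Particles are
proposed from the stochastic state-transition model (an efference copy of
the previous acceleration command with magnitude-dependent noise for the
own speed, and a zero-mean Gaussian acceleration prior for the leader) and
reweighted by the percept likelihood; systematic resampling is applied
every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KMH, PerceptionParams, PredictionParams
from .perception import Percept, percept_log_likelihood

__all__ = [
    "BeliefState",
    "DegeneratePosteriorError",
    "init_belief",
    "predict_step",
    "update_step",
    "systematic_resample",
    "belief_moments",
]

#: Default initial belief ranges: gap uniform on [5, 200] m and relative
#: speed uniform on [20, 60] km/h (the leader target-speed range).
INIT_D_RANGE = (5.0, 200.0)
INIT_R_RANGE = (20.0 * KMH, 60.0 * KMH)


class DegeneratePosteriorError(RuntimeError):
    """All particle weights vanished in a Bayes update."""


@dataclass
class BeliefState:
    """Weighted particle approximation of the scene-state posterior."""

    v: np.ndarray        #: own-speed particles, m/s
    d: np.ndarray        #: gap particles, m
    r: np.ndarray        #: relative-speed particles, m/s
    weights: np.ndarray  #: normalized weights, sum to 1

    @property
    def n(self) -> int:
        return self.v.size

    @property
    def v_leader(self) -> np.ndarray:
        """Per-particle leader speed ``v + r``."""
        return self.v + self.r

    def copy(self) -> "BeliefState":
        return BeliefState(self.v.copy(), self.d.copy(), self.r.copy(),
                           self.weights.copy())


def init_belief(v0: float, n: int, rng: np.random.Generator,
                d_range=INIT_D_RANGE, r_range=INIT_R_RANGE,
                leader_speed_prior: bool = False) -> BeliefState:
    """Initial belief: exact own speed, vague gap and relative speed.

    All particles start at the true own speed ``v0``; the gap is uniform
    on ``d_range`` and the relative speed uniform on ``r_range``.  With
    ``leader_speed_prior`` the uniform range is interpreted as a prior
    over *leader* speed instead, i.e. ``r = U(range) - v0`` (an alternative
    reading of the initial distribution; off by default).
    """
    if n < 1:
        raise ValueError("need at least one particle")
    v = np.full(n, float(v0))
    d = rng.uniform(d_range[0], d_range[1], size=n)
    r = rng.uniform(r_range[0], r_range[1], size=n)
    if leader_speed_prior:
        r = r - float(v0)
    w = np.full(n, 1.0 / n)
    return BeliefState(v, d, r, w)


def predict_step(belief: BeliefState, a_prev: float,
                 params: PredictionParams,
                 rng: np.random.Generator) -> BeliefState:
    """Propagate particles one step through the predicted dynamics.

    Per particle: the gap integrates the pre-update relative speed; own
    speed integrates an acceleration drawn around the efference copy
    ``a_prev`` with s.d. ``lambda_a * |a_prev|``; the leader's speed
    integrates a zero-mean acceleration with s.d. ``sigma_aL``; the new
    relative speed is the difference.  Weights are unchanged.  Predicted
    speeds are clamped at zero, mirroring the no-reversing world dynamics
    the driver is assumed to know.

    The two standard-normal blocks are drawn in a fixed order (own
    acceleration first, leader acceleration second) so trial records are
    reproducible.
    """
    dt = params.dt
    n = belief.n
    d_new = belief.d + belief.r * dt
    eps_a = rng.standard_normal(n)
    a_hat = a_prev + params.lambda_a * abs(a_prev) * eps_a
    v_new = np.maximum(0.0, belief.v + a_hat * dt)
    eps_L = rng.standard_normal(n)
    vL_new = np.maximum(0.0, (belief.v + belief.r)
                        + params.sigma_aL * eps_L * dt)
    r_new = vL_new - v_new
    return BeliefState(v_new, d_new, r_new, belief.weights.copy())


def update_step(belief: BeliefState, percept: Percept, occluded: bool,
                pparams: PerceptionParams) -> BeliefState:
    """Bayes reweighting by the percept likelihood.

    Weights are accumulated in log space with max-subtraction before
    exponentiation.  If every particle receives zero posterior weight the
    posterior is degenerate and an error is raised rather than silently
    resetting.
    """
    ll = percept_log_likelihood(percept, (belief.v, belief.d, belief.r),
                                occluded, pparams)
    with np.errstate(divide="ignore"):
        logw = np.log(belief.weights) + ll
    m = np.max(logw)
    if not np.isfinite(m):
        raise DegeneratePosteriorError(
            "all particle weights vanished in Bayes update")
    w = np.exp(logw - m)
    w /= np.sum(w)
    return BeliefState(belief.v, belief.d, belief.r, w)


def systematic_resample(belief: BeliefState,
                        rng: np.random.Generator) -> BeliefState:
    """Low-variance systematic resampling.

    One uniform offset positions an evenly spaced comb of ``N`` points
    over the cumulative weights; the offspring count of each particle is
    therefore either ``floor(N w)`` or ``ceil(N w)``.  Output weights are
    uniform.
    """
    n = belief.n
    u0 = rng.random()
    positions = (np.arange(n) + u0) / n
    cumw = np.cumsum(belief.weights)
    cumw[-1] = 1.0  # guard against rounding
    idx = np.searchsorted(cumw, positions, side="left")
    idx = np.minimum(idx, n - 1)
    w = np.full(n, 1.0 / n)
    return BeliefState(belief.v[idx], belief.d[idx], belief.r[idx], w)


def belief_moments(belief: BeliefState, g):
    """Weighted mean and s.d. of a per-particle scalar ``g``.

    ``g`` may be a callable applied to the belief or an array aligned with
    the particles.  The variance ``E[g^2] - E[g]^2`` is floored at zero
    against rounding.
    """
    gk = np.asarray(g(belief) if callable(g) else g, dtype=float)
    w = belief.weights
    mean = float(np.dot(w, gk))
    var = float(np.dot(w, gk * gk) - mean * mean)
    return mean, np.sqrt(max(var, 0.0))
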