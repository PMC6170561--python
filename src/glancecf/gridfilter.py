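"""Dense-grid Bayesian filter for validating the particle filter.

For the special case of a zero efference copy (``a_prev = 0``) the own
speed stays at its known initial value, so the belief lives on the
``(d, r)`` plane and exact sequential Bayesian inference is tractable on
a dense grid: the prediction step is a shear of the gap axis by ``r dt``
plus a Gaussian convolution of the relative-speed axis with s.d.
``sigma_aL dt``, and the update step is a pointwise multiplication by the
percept likelihood.  This module shares no code with the particle filter
and is used as an independent numerical oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .params import PerceptionParams, PredictionParams
from .perception import Percept

__all__ = ["GridFilter2D"]


class GridFilter2D:
    """Exact (grid-discretized) Bayes filter over (gap, relative speed)."""

    def __init__(self, v0: float, d_grid: np.ndarray, r_grid: np.ndarray,
                 d_prior, r_prior):
        """Uniform independent priors ``d ~ U(d_prior)``, ``r ~ U(r_prior)``.

        ``d_grid`` and ``r_grid`` are equally spaced cell centers that
        must cover the prior support plus the diffusion expected during
        filtering.
        """
        self.v0 = float(v0)
        self.d = np.asarray(d_grid, dtype=float)
        self.r = np.asarray(r_grid, dtype=float)
        self.hd = float(self.d[1] - self.d[0])
        self.hr = float(self.r[1] - self.r[0])
        pd = ((self.d >= d_prior[0]) & (self.d <= d_prior[1])).astype(float)
        pr = ((self.r >= r_prior[0]) & (self.r <= r_prior[1])).astype(float)
        self.density = np.outer(pd, pr)
        self.density /= self.density.sum()

    def predict(self, params: PredictionParams) -> None:
        """Shear the gap axis by ``r dt``; diffuse the relative speed."""
        dt = params.dt
        out = np.empty_like(self.density)
        for j, rj in enumerate(self.r):
            # density over d moves to d + r dt: evaluate old density at d - r dt
            out[:, j] = np.interp(self.d - rj * dt, self.d, self.density[:, j],
                                  left=0.0, right=0.0)
        sigma_cells = params.sigma_aL * dt / self.hr
        out = gaussian_filter1d(out, sigma_cells, axis=1, mode="constant")
        s = out.sum()
        if s <= 0:
            raise RuntimeError("grid filter density vanished in prediction")
        self.density = out / s

    def update(self, percept: Percept, occluded: bool,
               pparams: PerceptionParams) -> None:
        """Pointwise Bayes update by the percept likelihood.

        The likelihood is evaluated from the closed-form percept
        transforms and textbook normal densities (scipy), independently
        of the particle-filter code path.  The optic-flow term only
        involves the known own speed, so it is a constant and drops out.
        """
        dd, rr = np.meshgrid(self.d, self.r, indexing="ij")
        ll = np.zeros_like(dd)
        if not occluded:
            deg = 180.0 / np.pi
            phi = 2.0 * np.arctan(pparams.u / (2.0 * (dd + pparams.d0))) * deg
            vphi = (-4.0 * pparams.u * rr
                    / (4.0 * (dd + pparams.d0) ** 2 + pparams.u ** 2) * deg)
            ll = (norm.logpdf(percept.phi, phi, pparams.sigma_phi)
                  + norm.logpdf(percept.v_phi, vphi, pparams.sigma_vphi))
        ll -= np.max(ll)
        self.density = self.density * np.exp(ll)
        s = self.density.sum()
        if s <= 0:
            raise RuntimeError("grid filter density vanished in update")
        self.density /= s

    def posterior_means(self) -> tuple[float, float]:
        """Posterior means of (gap, relative speed) by midpoint sums."""
        md = float(np.sum(self.density.sum(axis=1) * self.d))
        mr = float(np.sum(self.density.sum(axis=0) * self.r))
        return md, mr
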