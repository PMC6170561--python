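"""Driver and simulation parameters.

The driver model has 13 driver-specific parameters: ten fixed from the
car-following and psychophysics literature, and three that are calibrated
per driver from behaviour (desired time headway ``T``, maximum desired
acceleration ``a_max`` and the acceleration-uncertainty threshold
``sigma_a_star``).  Defaults for the three calibrated parameters are
representative mid-range values and should normally be replaced by
calibrated estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

KMH = 1.0 / 3.6
"""Conversion factor from km/h to m/s."""


@dataclass(frozen=True)
class PerceptionParams:
    """Percept-space Gaussian noise magnitudes and optical geometry.

    Noise is constant in percept space (log speed, degrees, degrees per
    second), which makes the implied state-space noise grow with the
    magnitude of the state variable (Weber-Fechner-like behaviour).
    """

    sigma_F: float = 0.3      #: optic-flow (log speed) noise s.d., log units
    sigma_phi: float = 0.3    #: angular width noise s.d., degrees
    sigma_vphi: float = 0.3   #: angular expansion noise s.d., degrees/s
    u: float = 1.9            #: leading-vehicle width, m
    d0: float = 1.5           #: driver's distance to own front bumper, m
    v_floor: float = 0.1      #: speed clamp floor for log(v), m/s

    def validate(self) -> None:
        if min(self.sigma_F, self.sigma_phi, self.sigma_vphi) <= 0:
            raise ValueError("perception noise s.d. must be > 0")
        if self.u <= 0:
            raise ValueError("leader width u must be > 0")
        if self.d0 < 0:
            raise ValueError("front-bumper distance d0 must be >= 0")
        if self.v_floor <= 0:
            raise ValueError("v_floor must be > 0")


@dataclass(frozen=True)
class PredictionParams:
    """Stochastic state-transition (prediction) model parameters."""

    lambda_a: float = 0.1   #: efference-copy noise coefficient (dimensionless)
    sigma_aL: float = 4.0   #: expected leader acceleration s.d., m/s^2
    dt: float = 0.1         #: prediction timestep, s

    def validate(self) -> None:
        if self.lambda_a < 0:
            raise ValueError("lambda_a must be >= 0")
        if self.sigma_aL <= 0:
            raise ValueError("sigma_aL must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class IDMParams:
    """Intelligent Driver Model parameters.

    ``b_max`` defaults to ``a_max / 0.6`` when left as None, reflecting the
    systematic relation between comfortable acceleration and deceleration.
    """

    v_max: float = 80.0 * KMH  #: desired speed, m/s
    T: float = 1.5             #: desired time headway, s (calibrated)
    a_max: float = 1.5         #: maximum desired acceleration, m/s^2 (calibrated)
    b_max: float | None = None  #: maximum desired deceleration, m/s^2
    delta: float = 4.0         #: acceleration exponent
    s0: float = 2.0            #: jam distance, m
    s1: float = 0.0            #: jam distance second coefficient, m

    def __post_init__(self):
        if self.b_max is None:
            object.__setattr__(self, "b_max", self.a_max / 0.6)

    def validate(self) -> None:
        if min(self.v_max, self.T, self.a_max, self.b_max, self.delta) <= 0:
            raise ValueError("v_max, T, a_max, b_max and delta must be > 0")
        if self.s0 < 0 or self.s1 < 0:
            raise ValueError("jam distances must be >= 0")


@dataclass(frozen=True)
class AttentionParams:
    """Uncertainty-triggered visual sampling parameters."""

    sigma_a_star: float = 1.0  #: acceleration uncertainty threshold, m/s^2 (calibrated)
    t_G: float = 0.3           #: glance (unoccluded window) duration, s

    def validate(self) -> None:
        if self.sigma_a_star <= 0:
            raise ValueError("sigma_a_star must be > 0")
        if self.t_G <= 0:
            raise ValueError("t_G must be > 0")


@dataclass(frozen=True)
class DriverParams:
    """All driver-side parameters: perception, prediction, control, attention."""

    perception: PerceptionParams = field(default_factory=PerceptionParams)
    prediction: PredictionParams = field(default_factory=PredictionParams)
    idm: IDMParams = field(default_factory=IDMParams)
    attention: AttentionParams = field(default_factory=AttentionParams)

    def validate(self) -> None:
        self.perception.validate()
        self.prediction.validate()
        self.idm.validate()
        self.attention.validate()

    @classmethod
    def with_calibrated(cls, T: float, a_max: float, sigma_a_star: float,
                        **kwargs) -> "DriverParams":
        """Build defaults with the three calibrated parameters set.

        ``b_max`` follows ``a_max / 0.6``.
        """
        base = cls(**kwargs)
        return replace(
            base,
            idm=replace(base.idm, T=T, a_max=a_max, b_max=a_max / 0.6),
            attention=replace(base.attention, sigma_a_star=sigma_a_star),
        )
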