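"""Parameter containers for the receptive-field models and sine-wave probes.

All angles are in radians, measured counter-clockwise from the x1 axis.
The preferred orientation of a receptive field is phi; probing gratings are
inclined by theta relative to x1. Velocities are scalars along phi, i.e. the
2-vector velocity is v*(cos phi, sin phi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class STMode(str, Enum):
    """Spatio-temporal receptive-field structure."""

    SEPARABLE = "separable"
    VELOCITY_ADAPTED = "velocity_adapted"


@dataclass(frozen=True)
class SpatialRFParams:
    """Purely spatial affine Gaussian derivative receptive field.

    Parameters
    ----------
    sigma1 : float
        Spatial scale (standard deviation) along the preferred orientation.
    sigma2 : float
        Spatial scale perpendicular to the preferred orientation.
    phi : float
        Preferred orientation in radians.
    m : int
        Spatial derivative order along phi, in {0, 1, 2}.
    gamma : float
        Scale-normalization power; fixed at 1 (scale-invariant responses).
    """

    sigma1: float
    sigma2: float
    phi: float = 0.0
    m: int = 1
    gamma: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError(
                f"scales must be positive, got sigma1={self.sigma1}, "
                f"sigma2={self.sigma2}"
            )
        if self.m not in (0, 1, 2):
            raise ValueError(
                f"derivative order m={self.m} unsupported; only orders "
                "0, 1, 2 are modelled (higher orders are out of scope)"
            )
        if self.gamma != 1.0:
            raise ValueError(
                "scale-normalization power gamma is fixed at 1; other "
                "values are out of scope"
            )

    @property
    def kappa(self) -> float:
        """Scale parameter ratio sigma2/sigma1 (eccentricity = 1/kappa)."""
        return self.sigma2 / self.sigma1


@dataclass(frozen=True)
class SpatioTemporalRFParams:
    """Spatio-temporal affine Gaussian derivative receptive field.

    ``mode`` selects the space-time structure: a space-time separable filter
    (velocity treated as 0) factorizes into a spatial and a temporal kernel,
    while a velocity-adapted filter has its spatial profile translating with
    scalar velocity ``v`` along the preferred orientation.

    ``c`` is the distribution parameter (> 1) of the time-causal limit
    kernel, used only when evaluating that kernel's Fourier transform.
    """

    spatial: SpatialRFParams
    sigma_t: float
    v: float = 0.0
    n: int = 0
    mode: STMode = STMode.SEPARABLE
    c: float = math.sqrt(2.0)

    def __post_init__(self) -> None:
        if self.sigma_t <= 0:
            raise ValueError(f"sigma_t must be positive, got {self.sigma_t}")
        if self.n not in (0, 1, 2):
            raise ValueError(f"temporal order n={self.n} not in {{0,1,2}}")
        if self.c <= 1:
            raise ValueError(f"limit-kernel parameter c must exceed 1, got {self.c}")

    @property
    def velocity(self) -> float:
        """Effective scalar velocity (separable mode behaves as v = 0)."""
        return 0.0 if self.mode is STMode.SEPARABLE else self.v


@dataclass(frozen=True)
class SineProbe:
    """Probing sine grating.

    The spatial pattern is sin(omega*(cos(theta)*x1 + sin(theta)*x2) + beta);
    in the spatio-temporal case the phase gains a -omega*u*t term, so ``u``
    is the image velocity of the moving grating.
    """

    omega: float
    theta: float = 0.0
    beta: float = 0.0
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"angular frequency must be positive, got {self.omega}")


@dataclass(frozen=True)
class GaborParams:
    """Affine Gabor receptive-field pair (Gaussian envelope times carrier).

    The orientation-selectivity analysis depends on (sigma1, nu) only through
    the dimensionless product sigma1*nu.
    """

    sigma1: float
    sigma2: float
    nu: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gabor envelope scales must be positive")
        if self.nu <= 0:
            raise ValueError(f"carrier frequency nu must be positive, got {self.nu}")

    @property
    def kappa(self) -> float:
        return self.sigma2 / self.sigma1

    @property
    def sigma1nu(self) -> float:
        return self.sigma1 * self.nu


@dataclass(frozen=True)
class QuadratureConfig:
    """Weights of the quasi-quadrature energy combination.

    C_phi weights second- against first-order spatial derivative energy;
    C_t plays the same role temporally. Both default to 1/sqrt(2). The
    complementary scale-normalization power Gamma is fixed at 0.
    """

    C_phi: float = 1.0 / math.sqrt(2.0)
    C_t: float = 1.0 / math.sqrt(2.0)
    Gamma: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.C_phi <= 0 or self.C_t <= 0:
            raise ValueError("quadrature weights must be positive")
        if self.Gamma != 0.0:
            raise ValueError("Gamma is fixed at 0; other values are out of scope")
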