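"""Closed-form response amplitudes of the receptive-field models to sine
gratings, and the probe parameters (frequency, velocity) that maximize them.

The coordinate system is aligned with the preferred orientation (phi = 0),
so the grating inclination theta is measured relative to the receptive
field's preferred orientation. A linear filter maps the probing sine wave to
a phase-shifted wave of the same frequency; ``amplitude`` is the prefactor
of that response wave, reported nonnegative, and ``carrier`` records its
phase class (a first-order derivative turns the sine input into a cosine
wave, a second-order derivative returns a sine wave).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import SineProbe, SpatialRFParams, SpatioTemporalRFParams, STMode

__all__ = [
    "Carrier",
    "ResponseAmplitude",
    "spatial_amplitude",
    "optimal_frequency",
    "st_amplitude",
    "optimal_velocity",
    "st_optimal_frequency",
]


class Carrier(str, Enum):
    COSINE = "cosine"
    SINE = "sine"


@dataclass(frozen=True)
class ResponseAmplitude:
    amplitude: float
    carrier: Carrier

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


_MODEL_NUMERATOR = {
    "simple1": 1.0,
    "simple2": math.sqrt(2.0),
    "quadrature": 2.0 ** 0.25,
}


def spatial_amplitude(p: SpatialRFParams, probe: SineProbe) -> ResponseAmplitude:
    """Response amplitude of a purely spatial simple-cell model.

    m = 1: A = omega sigma1 |cos theta| exp(-omega^2 (s1^2 cos^2 + s2^2 sin^2)/2),
    carried on a cosine wave; m = 2: A = omega^2 sigma1^2 cos^2 theta times the
    same Gaussian factor, carried on a sine wave.
    """
    if p.m not in (1, 2):
        raise ValueError(
            "orientation-selective amplitudes are defined for derivative "
            f"orders 1 and 2, got m={p.m}"
        )
    w, th = probe.omega, probe.theta
    envelope = math.exp(
        -0.5
        * w
        * w
        * (p.sigma1**2 * math.cos(th) ** 2 + p.sigma2**2 * math.sin(th) ** 2)
    )
    if p.m == 1:
        return ResponseAmplitude(
            w * p.sigma1 * abs(math.cos(th)) * envelope, Carrier.COSINE
        )
    return ResponseAmplitude(
        w * w * p.sigma1**2 * math.cos(th) ** 2 * envelope, Carrier.SINE
    )


def optimal_frequency(
    sigma1: float, kappa: float, theta, model: str = "simple1"
):
    """Probe frequency maximizing the response at inclination theta.

    omega_hat = numerator / (sigma1 sqrt(cos^2 theta + kappa^2 sin^2 theta))
    with numerator 1 (first-order), sqrt(2) (second-order) or 2^{1/4} (the
    geometric mean of the two, used for the quasi-quadrature energy model).
    """
    try:
        numerator = _MODEL_NUMERATOR[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; expected one of {sorted(_MODEL_NUMERATOR)}"
        ) from None
    theta = np.asarray(theta, dtype=float)
    denom = sigma1 * np.sqrt(np.cos(theta) ** 2 + kappa**2 * np.sin(theta) ** 2)
    out = numerator / denom
    return out if out.shape else float(out)


def st_amplitude(p: SpatioTemporalRFParams, probe: SineProbe) -> ResponseAmplitude:
    """Response amplitude of a spatio-temporal simple-cell model to a
    moving grating with image velocity u.

    Velocity-adapted (n = 0, m in {1, 2}):
      A = (omega sigma1 |cos theta|)^m *
          exp(-omega^2/2 [ (s1^2 + st^2 v^2) cos^2 + s2^2 sin^2
                           - 2 st^2 u v cos theta + st^2 u^2 ]).

    Space-time separable (v = 0, n in {1, 2}): the 3-D convolution
    factorizes, giving the spatial amplitude times the temporal factor
    (omega u sigma_t)^n exp(-omega^2 u^2 sigma_t^2 / 2).
    """
    sp = p.spatial
    m = sp.m
    w, th, u = probe.omega, probe.theta, probe.u
    s1, s2, st = sp.sigma1, sp.sigma2, p.sigma_t
    if p.mode is STMode.VELOCITY_ADAPTED:
        if p.n != 0:
            raise ValueError("velocity-adapted amplitudes require temporal order n = 0")
        if m not in (1, 2):
            raise ValueError(f"spatial order m={m} must be 1 or 2")
        v = p.v
        expo = -0.5 * w * w * (
            (s1 * s1 + st * st * v * v) * math.cos(th) ** 2
            + s2 * s2 * math.sin(th) ** 2
            - 2.0 * st * st * u * v * math.cos(th)
            + st * st * u * u
        )
        amp = (w * s1 * abs(math.cos(th))) ** m * math.exp(expo)
        return ResponseAmplitude(amp, Carrier.COSINE if m == 1 else Carrier.SINE)
    # separable
    if p.v != 0.0:
        raise ValueError("separable mode requires v = 0")
    if p.n not in (1, 2):
        raise ValueError("separable-mode amplitudes are defined for temporal order 1 or 2")
    if m not in (1, 2):
        raise ValueError(f"spatial order m={m} must be 1 or 2")
    spatial = spatial_amplitude(sp, SineProbe(w, th)).amplitude
    temporal = (w * abs(u) * st) ** p.n * math.exp(-0.5 * w * w * u * u * st * st)
    # the response carrier class alternates with the total derivative order
    carrier = Carrier.COSINE if (m + p.n) % 2 == 1 else Carrier.SINE
    return ResponseAmplitude(spatial * temporal, carrier)


def optimal_velocity(p: SpatioTemporalRFParams, theta) -> float:
    """Probe velocity maximizing a velocity-adapted amplitude: u_hat = v cos theta."""
    if p.mode is not STMode.VELOCITY_ADAPTED:
        raise ValueError(
            "the closed-form optimal velocity holds for velocity-adapted "
            "receptive fields; use joint numeric maximization for the "
            "separable case"
        )
    theta = np.asarray(theta, dtype=float)
    out = p.v * np.cos(theta)
    return out if out.shape else float(out)


def st_optimal_frequency(
    p: SpatioTemporalRFParams, theta, model: str = "simple1"
):
    """Optimal probe frequency for spatio-temporal receptive fields.

    At the optimal velocity u_hat = v cos theta the temporal terms cancel
    from the stationarity condition, so the expression is identical to the
    purely spatial case (the same holds for the separable joint (omega, u)
    maximization).
    """
    sp = p.spatial
    return optimal_frequency(sp.sigma1, sp.kappa, theta, model)
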