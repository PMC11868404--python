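"""Compact orientation-selectivity measures: resultant R, circular
variance V = 1 - |R|, and orientation bandwidth B.

For a pi-periodic tuning curve r(theta) the resultant is the first circular
moment under doubled angles. The curves here are even in theta, so the
moment is computed on [-pi/2, pi/2] with the cos(2 theta) weight (the sine
part vanishes by symmetry and is asserted small when requested):

    R = integral r(t) cos(2t) dt / integral r(t) dt.

The bandwidth B is the smallest angle at which the peak-normalized curve
falls to 1/sqrt(2).

Closed forms for the first- and second-order simple-cell curves are
provided and cross-checked against quadrature; complex-cell measures are
defined by quadrature/root-finding only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

from .tuning_curves import SelectivityCurve, fixed_frequency_curve, canonical_curve

__all__ = [
    "TuningMeasures",
    "resultant",
    "circular_variance",
    "closed_form_resultant",
    "bandwidth",
    "closed_form_bandwidth",
    "lambda_resultant_simple1",
    "measures_for_curve",
]

_HALF_PI = math.pi / 2
_KAPPA_SINGULAR_TOL = 1e-4
_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class TuningMeasures:
    """Resultant, circular variance and bandwidth of one tuning curve."""

    R: float
    V: float
    B: float
    B_at_limit: bool = False  # True when r never falls below 1/sqrt(2)


def _as_callable(r) -> Callable[[float], float]:
    if isinstance(r, SelectivityCurve):
        return r
    if callable(r):
        return r
    raise TypeError("expected a SelectivityCurve or a callable r(theta)")


def resultant(r, *, check_symmetry: bool = False) -> float:
    """Quadrature resultant of a nonnegative curve on [-pi/2, pi/2].

    A sampled :class:`SelectivityCurve` is integrated by the trapezoid rule
    on its own theta grid (adaptive quadrature on the piecewise-linear
    interpolant would only chase roundoff); callables go through adaptive
    quadrature at absolute tolerance 1e-10.
    """
    if isinstance(r, SelectivityCurve):
        denom = float(np.trapezoid(r.values, r.thetas))
        if denom <= 1e-14:
            raise ValueError("degenerate curve: zero integral")
        numer = float(np.trapezoid(r.values * np.cos(2 * r.thetas), r.thetas))
        return numer / denom
    fn = _as_callable(r)
    denom, _ = integrate.quad(
        fn, -_HALF_PI, _HALF_PI, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200
    )
    if denom <= 1e-14:
        raise ValueError("degenerate curve: zero integral")
    numer, _ = integrate.quad(
        lambda t: fn(t) * math.cos(2 * t),
        -_HALF_PI,
        _HALF_PI,
        epsabs=_QUAD_TOL,
        epsrel=_QUAD_TOL,
        limit=200,
    )
    if check_symmetry:
        imag, _ = integrate.quad(
            lambda t: fn(t) * math.sin(2 * t),
            -_HALF_PI,
            _HALF_PI,
            epsabs=_QUAD_TOL,
            epsrel=_QUAD_TOL,
            limit=200,
        )
        if abs(imag / denom) > 1e-10:
            raise ValueError(
                f"curve is not symmetric: imaginary resultant part {imag / denom:g}"
            )
    return numer / denom


def circular_variance(R: float) -> float:
    """V = 1 - |R|."""
    if abs(R) > 1 + 1e-12:
        raise ValueError(f"|R| must not exceed 1, got {R}")
    return 1.0 - abs(R)


def closed_form_resultant(model: str, kappa: float) -> float:
    """Analytic resultant of the canonical simple-cell curves.

    simple1: k (k arccosh k - sqrt(k^2-1)) / ((k^2-1) arccosh k), which is
    singular at k = 1 where the analytic value is 1/3 (quadrature fallback
    near the singularity); simple2: k / (k + 1).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if model == "simple2":
        return kappa / (kappa + 1.0)
    if model != "simple1":
        raise ValueError(
            "closed-form resultants exist for the simple-cell models only"
        )
    if abs(kappa - 1.0) < _KAPPA_SINGULAR_TOL:
        return resultant(lambda t: canonical_curve("simple1", "spatial", kappa, t))
    if kappa < 1:
        # arccosh is undefined below 1; quadrature remains valid
        return resultant(lambda t: canonical_curve("simple1", "spatial", kappa, t))
    acosh = math.acosh(kappa)
    return (
        kappa
        * (kappa * acosh - math.sqrt(kappa**2 - 1.0))
        / ((kappa**2 - 1.0) * acosh)
    )


def bandwidth(r, *, tol: float = 1e-10) -> tuple[float, bool]:
    """Smallest B in (0, pi/2] with r(B) = 1/sqrt(2) (r peak-normalized).

    Returns (B, at_limit); at_limit is True when the curve never drops below
    1/sqrt(2), in which case B = pi/2.
    """
    fn = _as_callable(r)
    target = 1.0 / math.sqrt(2.0)
    r0 = float(fn(0.0))
    if abs(r0 - 1.0) > 1e-8:
        raise ValueError(f"bandwidth requires a peak-normalized curve, r(0) = {r0}")

    def g(t: float) -> float:
        return float(fn(t)) - target

    # locate the first sign change on a fine scan, then refine
    ts = np.linspace(0.0, _HALF_PI, 2049)
    vals = np.array([g(t) for t in ts])
    below = np.nonzero(vals < 0)[0]
    if below.size == 0:
        return _HALF_PI, True
    i = below[0]
    if i == 0:
        raise ValueError("curve starts below 1/sqrt(2); not peak-normalized")
    b = optimize.brentq(g, ts[i - 1], ts[i], xtol=tol)
    return float(b), False


def closed_form_bandwidth(model: str, kappa: float) -> float:
    """Analytic bandwidth of the canonical simple-cell curves.

    simple1: arccos(k / sqrt(k^2 + 1)); simple2: the two-argument arctan
    expression obtained by solving cos^2/(cos^2 + k^2 sin^2) = 1/sqrt(2).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if model == "simple1":
        return math.acos(kappa / math.sqrt(kappa**2 + 1.0))
    if model != "simple2":
        raise ValueError("closed-form bandwidths exist for the simple-cell models only")
    s2 = math.sqrt(2.0)
    inner = (-2 * s2 * kappa**2 + 2 * s2 * math.sqrt(kappa**2 + s2 - 1.0) * kappa + s2 - 2.0) / (
        s2 - 2.0
    )
    return 2.0 * math.atan(math.sqrt(inner))


def lambda_resultant_simple1(kappa: float, lam: float) -> float:
    """Resultant of the fixed-frequency first-order curve.

    R = 2 sqrt(2/pi) e^{-(k^2-1) l^2 / 2}
        / (sqrt(k^2-1) l erf(sqrt(k^2-1) l / sqrt(2)))
        - 2 / ((k^2-1) l^2) + 1,
    with a quadrature fallback at the k -> 1 singularity (there the curve is
    |cos| and R = 1/3 regardless of lambda).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if abs(kappa - 1.0) < _KAPPA_SINGULAR_TOL:
        return resultant(lambda t: fixed_frequency_curve("simple1", kappa, lam, t))
    a = (kappa**2 - 1.0) * lam**2
    return (
        2.0
        * math.sqrt(2.0 / math.pi)
        * math.exp(-0.5 * a)
        / (math.sqrt(kappa**2 - 1.0) * lam * special.erf(math.sqrt(a / 2.0)))
        - 2.0 / a
        + 1.0
    )


def measures_for_curve(r) -> TuningMeasures:
    """Resultant, circular variance and bandwidth from one curve object."""
    R = resultant(r)
    B, at_limit = bandwidth(r)
    return TuningMeasures(R=R, V=circular_variance(R), B=B, B_at_limit=at_limit)
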