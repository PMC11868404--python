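"""Normalized orientation-selectivity curves for simple and complex cell
models, including the probe-mismatch (perturbation) variants.

Every public curve is peak-normalized to r(0) = 1, matching the convention
of reporting responses relative to the maximum obtained at the preferred
orientation. Raw-amplitude variants (with their 1/sqrt(e), 2/e and
2^{1/4} e^{-1/sqrt(2)} prefactors) are exposed for oracle tests.

Probing protocols
-----------------
adapted                      probe frequency (and velocity) optimal per theta
lambda_scaled                frequency = lambda * optimal(theta); the
                             normalized curve is lambda-independent
fixed_frequency              frequency fixed at its theta = 0 optimum times
                             lambda, not re-adapted per orientation
velocity_mismatch            velocity-adapted probing with u = mu v cos theta;
                             kappa is replaced by an effective kappa_tilde
fixed_frequency_and_velocity neither frequency nor velocity adapted per theta
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (
    QuadratureConfig,
    SineProbe,
    SpatialRFParams,
    SpatioTemporalRFParams,
    STMode,
)
from .probe_response import optimal_frequency, spatial_amplitude, st_amplitude

__all__ = [
    "SelectivityCurve",
    "default_thetas",
    "canonical_curve",
    "raw_peak_amplitude",
    "quadrature_curve_from_amplitudes",
    "lambda_scaled_curve",
    "fixed_frequency_curve",
    "velocity_mismatch_curve",
    "effective_kappa",
    "fixed_frequency_and_velocity_curve",
    "sample_curve",
]

MODELS = ("simple1", "simple2", "complex")
RF_CLASSES = ("spatial", "separable", "velocity_adapted")


def default_thetas(n: int = 181) -> np.ndarray:
    """Uniform inclination-angle grid on [-pi/2, pi/2]."""
    return np.linspace(-math.pi / 2, math.pi / 2, n)


@dataclass(frozen=True)
class SelectivityCurve:
    """Sampled normalized tuning curve r(theta) with model metadata."""

    thetas: np.ndarray
    values: np.ndarray
    model: str
    rf_class: str = "spatial"
    kappa: float = 1.0
    probing: str = "adapted"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.thetas.shape:
            raise ValueError("thetas and values must have matching shapes")

    def __call__(self, theta):
        return np.interp(theta, self.thetas, self.values)


def _denominator(theta: np.ndarray, kappa: float) -> np.ndarray:
    return np.cos(theta) ** 2 + kappa**2 * np.sin(theta) ** 2


def canonical_curve(model: str, rf_class: str, kappa: float, theta):
    """Canonical normalized orientation-selectivity curves.

    simple1 (all classes):  |cos| / sqrt(cos^2 + k^2 sin^2)
    simple2 (all classes):  cos^2 / (cos^2 + k^2 sin^2)
    complex, spatial & velocity-adapted:
                            |cos|^{3/2} / (cos^2 + k^2 sin^2)^{3/4}
    complex, separable:     |cos| sqrt(2 + k^2 + (2 - k^2) cos 2t)
                            / (cos^2 + k^2 sin^2), divided by its theta = 0
                            value (2) so the returned curve peaks at 1.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if rf_class not in RF_CLASSES:
        raise ValueError(f"unknown rf_class {rf_class!r}; expected one of {RF_CLASSES}")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    import warnings

    if kappa < 1:
        warnings.warn(
            "kappa < 1 means the receptive field is elongated along the "
            "probing axis; curves are defined but the narrowing analysis "
            "assumes kappa >= 1",
            stacklevel=2,
        )
    theta = np.asarray(theta, dtype=float)
    d = _denominator(theta, kappa)
    c = np.abs(np.cos(theta))
    if model == "simple1":
        out = c / np.sqrt(d)
    elif model == "simple2":
        out = c * c / d
    elif rf_class in ("spatial", "velocity_adapted"):
        out = c ** 1.5 / d**0.75
    else:  # complex separable
        out = c * np.sqrt(2 + kappa**2 + (2 - kappa**2) * np.cos(2 * theta)) / d / 2.0
    return out if out.shape else float(out)


def raw_peak_amplitude(model: str, rf_class: str = "spatial") -> float:
    """Theta = 0 value of the un-normalized adapted-probe amplitude.

    1/sqrt(e) for first-order, 2/e for second-order simple cells, and
    2^{1/4} e^{-1/sqrt(2)} for the quasi-quadrature complex-cell measure.
    """
    if model == "simple1":
        return math.exp(-0.5)
    if model == "simple2":
        return 2.0 / math.e
    if model == "complex":
        return 2.0**0.25 * math.exp(-1.0 / math.sqrt(2.0))
    raise ValueError(f"unknown model {model!r}")


def _quadrature_amplitudes(
    rf_class: str,
    kappa: float,
    theta: float,
    sigma1: float = 1.0,
    sigma_t: float = 1.0,
    v: float = 1.0,
    omega: float | None = None,
    u: float | None = None,
):
    """First- and second-order amplitudes entering the energy combination."""
    if omega is None:
        omega = float(optimal_frequency(sigma1, kappa, theta, "quadrature"))
    if rf_class == "spatial":
        p1 = SpatialRFParams(sigma1, kappa * sigma1, m=1)
        p2 = SpatialRFParams(sigma1, kappa * sigma1, m=2)
        probe = SineProbe(omega, theta)
        return (
            spatial_amplitude(p1, probe).amplitude,
            spatial_amplitude(p2, probe).amplitude,
        )
    if rf_class == "velocity_adapted":
        if u is None:
            u = v * math.cos(theta)
        sp1 = SpatialRFParams(sigma1, kappa * sigma1, m=1)
        sp2 = SpatialRFParams(sigma1, kappa * sigma1, m=2)
        st1 = SpatioTemporalRFParams(sp1, sigma_t, v=v, n=0, mode=STMode.VELOCITY_ADAPTED)
        st2 = SpatioTemporalRFParams(sp2, sigma_t, v=v, n=0, mode=STMode.VELOCITY_ADAPTED)
        probe = SineProbe(omega, theta, u=u)
        return (
            st_amplitude(st1, probe).amplitude,
            st_amplitude(st2, probe).amplitude,
        )
    raise ValueError(
        "quasi-quadrature curves are defined for the spatial and "
        f"velocity-adapted classes, got {rf_class!r}"
    )


def _geometric_mean_of_extremes(a1: float, a2: float, c_phi: float) -> float:
    """Collapse the phase ripple of Q = sqrt(A1^2 cos^2 psi + C A2^2 sin^2 psi).

    The extremes over the response phase psi are A1 and sqrt(C) A2; their
    geometric mean sqrt(A1 sqrt(C) A2) is the representative energy value.
    """
    return math.sqrt(a1 * math.sqrt(c_phi) * a2)


def quadrature_curve_from_amplitudes(
    rf_class: str,
    kappa: float,
    theta,
    cfg: QuadratureConfig | None = None,
    sigma1: float = 1.0,
    sigma_t: float = 1.0,
    v: float = 1.0,
):
    """Complex-cell curve recomputed from the quasi-quadrature construction.

    Probes at the geometric-mean optimal frequency (and, for the
    velocity-adapted class, at u_hat = v cos theta), combines the first- and
    second-order amplitudes into the energy measure, collapses the phase
    ripple by the geometric mean of its extremes, and peak-normalizes.
    Agrees with ``canonical_curve('complex', ...)`` to quadrature precision.
    """
    if cfg is None:
        cfg = QuadratureConfig()
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))

    def one(th: float) -> float:
        a1, a2 = _quadrature_amplitudes(rf_class, kappa, th, sigma1, sigma_t, v)
        return _geometric_mean_of_extremes(a1, a2, cfg.C_phi)

    vals = np.array([one(th) for th in theta_arr])
    vals = vals / one(0.0)
    return vals if np.ndim(theta) else float(vals[0])


def lambda_scaled_curve(model: str, kappa: float, lam: float, theta):
    """Adapted probing with frequency scaled by lambda > 0.

    The lambda factor cancels under peak normalization, so the curve equals
    the canonical one for every lambda.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if model not in ("simple1", "simple2"):
        raise ValueError("lambda-scaled curves are defined for simple-cell models")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    m = 1 if model == "simple1" else 2
    p = SpatialRFParams(1.0, kappa, m=m)

    def amp(th: float) -> float:
        omega = lam * float(optimal_frequency(1.0, kappa, th, model))
        return spatial_amplitude(p, SineProbe(omega, th)).amplitude

    vals = np.array([amp(th) for th in theta_arr]) / amp(0.0)
    return vals if np.ndim(theta) else float(vals[0])


def fixed_frequency_curve(
    model: str,
    kappa: float,
    lam: float,
    theta,
    cfg: QuadratureConfig | None = None,
):
    """Probing at a theta-independent frequency (lambda times the theta = 0
    optimum: lambda/s1, sqrt(2) lambda/s1 or 2^{1/4} lambda/s1).

    Closed forms for the simple cells:
      simple1: exp(-(k^2-1) lambda^2 sin^2 / 2) |cos|
      simple2: exp(-(k^2-1) lambda^2 sin^2) cos^2
    The complex-cell curve is computed numerically from the amplitude
    formulas and peak-normalized.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if model == "simple1":
        vals = np.exp(-0.5 * (kappa**2 - 1) * lam**2 * np.sin(theta_arr) ** 2) * np.abs(
            np.cos(theta_arr)
        )
    elif model == "simple2":
        vals = np.exp(-(kappa**2 - 1) * lam**2 * np.sin(theta_arr) ** 2) * np.cos(
            theta_arr
        ) ** 2
    elif model == "complex":
        if cfg is None:
            cfg = QuadratureConfig()
        omega = 2.0**0.25 * lam  # sigma1 = 1

        def one(th: float) -> float:
            a1, a2 = _quadrature_amplitudes("spatial", kappa, th, omega=omega)
            return _geometric_mean_of_extremes(a1, a2, cfg.C_phi)

        vals = np.array([one(th) for th in theta_arr])
        vals = vals / one(0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return vals if np.ndim(theta) else float(vals[0])


def effective_kappa(
    kappa: float, mu: float, sigma1: float, sigma_t: float, v: float
) -> float:
    """Effective scale ratio under velocity-mismatched probing.

    kappa_tilde^2 = kappa^2 / (1 + (mu - 1)^2 vtilde^2), with the
    scale-normalized velocity vtilde = sigma_t v / sigma1. mu = 1 recovers
    kappa.
    """
    vtilde = sigma_t * v / sigma1
    return kappa / math.sqrt(1.0 + (mu - 1.0) ** 2 * vtilde**2)


def velocity_mismatch_curve(
    model: str,
    kappa: float,
    mu: float,
    sigma1: float,
    sigma_t: float,
    v: float,
    theta,
):
    """Velocity-adapted probing with u = mu v cos theta (frequency adapted).

    After peak normalization the curve is the canonical simple-cell curve
    with kappa replaced by the effective kappa_tilde; mu = 1 reduces to the
    adapted case.
    """
    if model not in ("simple1", "simple2"):
        raise ValueError("velocity-mismatch curves are defined for simple-cell models")
    kt = effective_kappa(kappa, mu, sigma1, sigma_t, v)
    return canonical_curve(model, "spatial", kt, theta)


def velocity_mismatch_curve_from_amplitudes(
    model: str,
    kappa: float,
    mu: float,
    sigma1: float,
    sigma_t: float,
    v: float,
    theta,
    lam: float = 1.0,
):
    """Direct amplitude-evaluation route for the velocity-mismatch curve.

    Probes with u = mu v cos theta and, per orientation, the frequency that
    maximizes the response given that velocity: omega = lambda * numerator /
    sqrt(s1_eff^2 cos^2 + s2^2 sin^2) with s1_eff^2 = s1^2 + (mu-1)^2 st^2 v^2
    (which reduces to the adapted frequency at mu = 1). Peak-normalizes;
    used as an independent check that the kappa_tilde reduction is exact
    (the normalized curve is lambda-independent).
    """
    m = 1 if model == "simple1" else 2
    sp = SpatialRFParams(sigma1, kappa * sigma1, m=m)
    p = SpatioTemporalRFParams(sp, sigma_t, v=v, n=0, mode=STMode.VELOCITY_ADAPTED)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    numerator = 1.0 if m == 1 else math.sqrt(2.0)
    s1_eff_sq = sigma1**2 + (mu - 1.0) ** 2 * sigma_t**2 * v**2

    def amp(th: float) -> float:
        denom = math.sqrt(
            s1_eff_sq * math.cos(th) ** 2 + (kappa * sigma1) ** 2 * math.sin(th) ** 2
        )
        omega = lam * numerator / denom
        u = mu * v * math.cos(th)
        return st_amplitude(p, SineProbe(omega, th, u=u)).amplitude

    vals = np.array([amp(th) for th in theta_arr]) / amp(0.0)
    return vals if np.ndim(theta) else float(vals[0])


def fixed_frequency_and_velocity_curve(
    model: str,
    kappa: float,
    lam: float,
    mu: float,
    sigma1: float,
    sigma_t: float,
    v: float,
    theta,
):
    """Probing with theta-independent frequency and velocity.

    omega = lambda * numerator / sqrt((mu-1)^2 st^2 v^2 + s1^2) (numerator 1
    or sqrt(2) for first-/second-order) and u = mu v, i.e. the values that
    would be optimal at theta = 0; the curve is evaluated numerically from
    the velocity-adapted amplitudes and peak-normalized. With v = 0 it
    reduces to the purely spatial fixed-frequency curve.
    """
    if model not in ("simple1", "simple2"):
        raise ValueError(
            "fixed-frequency-and-velocity curves are defined for simple-cell models"
        )
    if lam <= 0:
        raise ValueError("lambda must be positive")
    m = 1 if model == "simple1" else 2
    numerator = 1.0 if m == 1 else math.sqrt(2.0)
    omega = lam * numerator / math.sqrt((mu - 1.0) ** 2 * sigma_t**2 * v**2 + sigma1**2)
    u = mu * v
    sp = SpatialRFParams(sigma1, kappa * sigma1, m=m)
    p = SpatioTemporalRFParams(sp, sigma_t, v=v, n=0, mode=STMode.VELOCITY_ADAPTED)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))

    def amp(th: float) -> float:
        return st_amplitude(p, SineProbe(omega, th, u=u)).amplitude

    vals = np.array([amp(th) for th in theta_arr]) / amp(0.0)
    return vals if np.ndim(theta) else float(vals[0])


def sample_curve(
    model: str,
    rf_class: str = "spatial",
    kappa: float = 1.0,
    probing: str = "adapted",
    thetas: np.ndarray | None = None,
    **kwargs,
) -> SelectivityCurve:
    """Build a :class:`SelectivityCurve` for any probing protocol.

    Extra keyword arguments are forwarded to the protocol-specific curve
    function (lam, mu, sigma1, sigma_t, v, cfg).
    """
    if thetas is None:
        thetas = default_thetas()
    if probing == "adapted":
        values = np.asarray(canonical_curve(model, rf_class, kappa, thetas))
    elif probing == "lambda_scaled":
        values = np.asarray(
            lambda_scaled_curve(model, kappa, kwargs.pop("lam", 1.0), thetas)
        )
    elif probing == "fixed_frequency":
        values = np.asarray(
            fixed_frequency_curve(
                model, kappa, kwargs.pop("lam", 1.0), thetas, kwargs.pop("cfg", None)
            )
        )
    elif probing == "velocity_mismatch":
        values = np.asarray(
            velocity_mismatch_curve(
                model,
                kappa,
                kwargs.pop("mu", 1.0),
                kwargs.pop("sigma1", 1.0),
                kwargs.pop("sigma_t", 1.0),
                kwargs.pop("v", 1.0),
                thetas,
            )
        )
    elif probing == "fixed_frequency_and_velocity":
        values = np.asarray(
            fixed_frequency_and_velocity_curve(
                model,
                kappa,
                kwargs.pop("lam", 1.0),
                kwargs.pop("mu", 1.0),
                kwargs.pop("sigma1", 1.0),
                kwargs.pop("sigma_t", 1.0),
                kwargs.pop("v", 1.0),
                thetas,
            )
        )
    else:
        raise ValueError(f"unknown probing protocol {probing!r}")
    if kwargs:
        raise TypeError(f"unused arguments for probing={probing!r}: {sorted(kwargs)}")
    return SelectivityCurve(
        thetas=np.asarray(thetas, dtype=float),
        values=values,
        model=model,
        rf_class=rf_class,
        kappa=kappa,
        probing=probing,
    )
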