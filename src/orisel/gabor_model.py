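"""Affine Gabor receptive-field pair: kernels, sine-probe responses,
quadrature energy, and orientation-selectivity curves.

The pair consists of a Gaussian envelope with scales (sigma1, sigma2)
multiplied by cos(nu x1) (even) or sin(nu x1) (odd). Unlike the Gaussian
derivative analysis, the probe frequency is not re-optimized per
orientation: the probe is fixed at omega = nu, so the selectivity depends
on sigma1 and nu only through the dimensionless product sigma1*nu (in
addition to kappa = sigma2/sigma1).

Closed-form responses to the grating
sin(omega cos(theta) x1 + omega sin(theta) x2 + beta), with
a = nu omega sigma1^2 and the shared envelope
E = exp(-(nu^2 s1^2 + 2 a cos t + omega^2 s1^2 cos^2 t + omega^2 s2^2 sin^2 t)/2):

    L_even =  (1/2) (e^{2 a cos t} + 1) E sin(phase)
    L_odd  = -(1/2) (e^{2 a cos t} - 1) E cos(phase)

so the even filter responds on the sine carrier and the odd filter on the
cosine carrier. At omega = nu the amplitudes reduce to

    A_even/odd(t) = (1/2)(e^{2 nu^2 s1^2 cos t} +/- 1)
                    * exp(-nu^2 s1^2 cos^2(t/2) [(k^2-1)(1-cos t) + 2]),

verified here against both the spatial-domain responses and a rendered-
grating oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

from .params import GaborParams

__all__ = [
    "eval_gabor",
    "gabor_responses",
    "gabor_amplitudes",
    "gabor_energy",
    "gabor_energy_from_responses",
    "gabor_selectivity_curve",
    "gabor_bandwidth",
]


def eval_gabor(x1, x2, p: GaborParams, parity: str = "even"):
    """Gabor kernel value: normalized Gaussian envelope times carrier."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    env = np.exp(-x1 * x1 / (2 * p.sigma1**2) - x2 * x2 / (2 * p.sigma2**2)) / (
        2 * math.pi * p.sigma1 * p.sigma2
    )
    if parity == "even":
        return env * np.cos(p.nu * x1)
    if parity == "odd":
        return env * np.sin(p.nu * x1)
    raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")


def _shared_exponent(theta, sigma1, sigma2, nu, omega):
    return 0.5 * (
        -(nu**2) * sigma1**2
        - 2 * nu * omega * sigma1**2 * np.cos(theta)
        - omega**2 * sigma1**2 * np.cos(theta) ** 2
        - omega**2 * sigma2**2 * np.sin(theta) ** 2
    )


def gabor_responses(
    x1, x2, theta: float, p: GaborParams, beta: float = 0.0, omega: float | None = None
):
    """Closed-form responses (L_even, L_odd) of the pair to the grating."""
    if omega is None:
        omega = p.nu
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    phase = beta + omega * x1 * np.cos(theta) + omega * x2 * np.sin(theta)
    shared = np.exp(_shared_exponent(theta, p.sigma1, p.sigma2, p.nu, omega))
    bump = np.exp(2 * p.nu * omega * p.sigma1**2 * np.cos(theta))
    l_even = 0.5 * (bump + 1.0) * shared * np.sin(phase)
    l_odd = -0.5 * (bump - 1.0) * shared * np.cos(phase)
    return l_even, l_odd


def gabor_amplitudes(theta, sigma1: float, kappa: float, nu: float):
    """Response amplitudes (A_even, A_odd) at probe frequency omega = nu.

    Depend on (sigma1, nu) only through a = (sigma1 nu)^2:
      A_even/odd = (1/2)(e^{2 a cos t} +/- 1)
                   e^{-a cos^2(t/2) [(k^2-1)(1 - cos t) + 2]}.
    """
    theta = np.asarray(theta, dtype=float)
    a = (sigma1 * nu) ** 2
    ct = np.cos(theta)
    half = np.cos(theta / 2.0) ** 2
    env = np.exp(-a * half * ((kappa**2 - 1.0) * (1.0 - ct) + 2.0))
    a_even = 0.5 * (np.exp(2 * a * ct) + 1.0) * env
    a_odd = 0.5 * np.abs(np.exp(2 * a * ct) - 1.0) * env
    if a_even.shape:
        return a_even, a_odd
    return float(a_even), float(a_odd)


def gabor_energy(
    x1,
    x2,
    theta: float,
    sigma1: float,
    kappa: float,
    nu: float,
    beta: float = 0.0,
):
    """Quadrature energy Q^2 of the Gabor pair at probe frequency nu.

    Expanded closed form A_even^2 sin^2(phase) + A_odd^2 cos^2(phase);
    equals the sum of squares of the two responses identically.
    """
    a_even, a_odd = gabor_amplitudes(theta, sigma1, kappa, nu)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    phase = beta + nu * x1 * np.cos(theta) + nu * x2 * np.sin(theta)
    mean = 0.5 * (a_even**2 + a_odd**2)
    ripple = 0.5 * (a_even**2 - a_odd**2)
    return mean - ripple * np.cos(2 * phase)


def gabor_energy_from_responses(
    x1,
    x2,
    theta: float,
    sigma1: float,
    kappa: float,
    nu: float,
    beta: float = 0.0,
):
    """Independent route: L_even^2 + L_odd^2 from the response expressions."""
    p = GaborParams(sigma1, kappa * sigma1, nu)
    l_even, l_odd = gabor_responses(x1, x2, theta, p, beta=beta)
    return l_even**2 + l_odd**2


def _energy_stats(theta: float, sigma1: float, kappa: float, nu: float):
    """Spatial mean and geometric-mean-of-extremes of Q over one period."""
    a_even, a_odd = gabor_amplitudes(theta, sigma1, kappa, nu)

    def q(w: float) -> float:
        return math.sqrt((a_even * math.sin(w)) ** 2 + (a_odd * math.cos(w)) ** 2)

    mean, _ = integrate.quad(q, 0.0, 2 * math.pi, epsabs=1e-12, epsrel=1e-12, limit=200)
    mean /= 2 * math.pi
    geo = math.sqrt(max(a_even, a_odd) * min(a_even, a_odd))
    return mean, geo


def gabor_selectivity_curve(
    parity: str,
    kappa: float,
    sigma1nu: float,
    theta,
    energy_collapse: str = "mean",
):
    """Peak-normalized orientation-selectivity curve of the Gabor model.

    parity 'even'/'odd': A_parity(theta)/A_parity(0). parity 'energy': the
    phase ripple of Q is collapsed either by the spatial mean over one
    carrier period ('mean') or by the geometric mean of its extremes
    ('extremes'), then peak-normalized.
    """
    if sigma1nu <= 0:
        raise ValueError("sigma1nu must be positive")
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if parity in ("even", "odd"):
        a_e, a_o = gabor_amplitudes(theta_arr, 1.0, kappa, sigma1nu)
        a0_e, a0_o = gabor_amplitudes(0.0, 1.0, kappa, sigma1nu)
        vals = a_e / a0_e if parity == "even" else a_o / a0_o
    elif parity == "energy":
        idx = 0 if energy_collapse == "mean" else 1
        if energy_collapse not in ("mean", "extremes"):
            raise ValueError("energy_collapse must be 'mean' or 'extremes'")
        vals = np.array(
            [_energy_stats(th, 1.0, kappa, sigma1nu)[idx] for th in theta_arr]
        )
        vals = vals / _energy_stats(0.0, 1.0, kappa, sigma1nu)[idx]
    else:
        raise ValueError(f"parity must be 'even', 'odd' or 'energy', got {parity!r}")
    return vals if np.ndim(theta) else float(vals[0])


def discretize_gabor(
    sigma1: float,
    kappa: float,
    nu: float,
    parity: str,
    n_sigma: float = 5.0,
    steps_per_sigma: float = 8.0,
):
    """Sample a Gabor kernel on a grid resolving both envelope and carrier."""
    from .rf_kernels import make_grid

    p = GaborParams(sigma1, kappa * sigma1, nu)
    h = min(
        min(p.sigma1, p.sigma2) / steps_per_sigma, 2 * math.pi / nu / 16.0
    )
    grid = make_grid(
        ((-n_sigma * p.sigma1, n_sigma * p.sigma1),
         (-n_sigma * p.sigma2, n_sigma * p.sigma2)),
        (h, h),
    )
    mesh = grid.meshgrid()
    return grid.with_values(eval_gabor(mesh[0], mesh[1], p, parity))


def gabor_bandwidth(parity: str, kappa: float, sigma1nu: float) -> float:
    """Bandwidth of the Gabor selectivity curve (angle where it hits 1/sqrt 2)."""
    from .tuning_measures import bandwidth

    b, _ = bandwidth(lambda t: gabor_selectivity_curve(parity, kappa, sigma1nu, t))
    return b
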