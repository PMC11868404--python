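"""Independent brute-force verification layer.

Everything here avoids the closed forms it is used to check: stimuli are
rendered sine gratings on rasters, responses are discrete inner products of
sampled kernels with those rasters, optima are found by numeric search, and
integrals/roots by adaptive quadrature and bracketed root-finding. All
computations are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .params import SineProbe
from .rf_kernels import RasterGrid

__all__ = [
    "StimulusSpec",
    "EmpiricalAmplitude",
    "render_stimulus",
    "empirical_amplitude",
    "argmax_frequency",
    "argmax_frequency_velocity",
    "quadrature",
    "find_root",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Probing grating plus the raster it is rendered on (contrast 1)."""

    probe: SineProbe
    grid: RasterGrid

    def __post_init__(self) -> None:
        # >= 8 samples per carrier period: the phase advance per grid step
        # along every axis must stay below 2 pi / 8
        probe = self.probe
        wavevec = [
            probe.omega * math.cos(probe.theta),
            probe.omega * math.sin(probe.theta),
        ]
        if self.grid.ndim == 3:
            wavevec.append(probe.omega * probe.u)
        max_phase_step = max(
            abs(k) * h for k, h in zip(wavevec, self.grid.steps)
        )
        if max_phase_step > 2 * math.pi / 8.0:
            raise ValueError(
                f"stimulus under-sampled: phase advance {max_phase_step:g} per "
                f"grid step exceeds 2 pi / 8 = {2 * math.pi / 8:g}"
            )


def _phase_field(spec: StimulusSpec) -> np.ndarray:
    probe = spec.probe
    mesh = spec.grid.meshgrid()
    phase = probe.omega * (
        math.cos(probe.theta) * mesh[0] + math.sin(probe.theta) * mesh[1]
    )
    if spec.grid.ndim == 3:
        phase = phase - probe.omega * probe.u * mesh[2]
    return phase


def render_stimulus(spec: StimulusSpec) -> RasterGrid:
    """Raster of sin(omega (cos t x1 + sin t x2 [- u t']) + beta)."""
    return spec.grid.with_values(np.sin(_phase_field(spec) + spec.probe.beta))


@dataclass(frozen=True)
class EmpiricalAmplitude:
    """Amplitude measured by sweeping the stimulus phase beta.

    The response of a linear filter at the grid center is sinusoidal in
    beta; ``amplitude`` is half the peak-to-trough of that sweep,
    ``phase_offset`` the fitted phase, and ``fit_residual`` the relative RMS
    deviation of the sweep from the fitted sinusoid (zero up to rounding for
    a truly linear measurement chain).
    """

    amplitude: float
    phase_offset: float
    fit_residual: float


def empirical_amplitude(
    rf_raster: RasterGrid,
    probe: SineProbe,
    n_phases: int = 8,
    max_residual: float = 1e-3,
) -> EmpiricalAmplitude:
    """Measure the response amplitude of a sampled kernel to a grating.

    Evaluates the convolution at the grid center only (translation
    invariance makes one point sufficient): response(beta) =
    sum_x T(x) f(-x) * cellvolume, for a sweep of phases beta, then fits
    A sin(beta + delta) by least squares.
    """
    if rf_raster.values is None:
        raise ValueError("kernel raster has no sampled values")
    spec = StimulusSpec(probe, rf_raster)
    # f(-x): flip the phase field sign
    phase = -_phase_field(spec)
    betas = 2 * math.pi * np.arange(n_phases) / n_phases
    t = rf_raster.values
    vol = rf_raster.cell_volume
    responses = np.array(
        [float((t * np.sin(phase + b)).sum()) * vol for b in betas]
    )
    # least-squares fit responses ~ S sin(beta) + C cos(beta)
    design = np.column_stack([np.sin(betas), np.cos(betas)])
    (s, c), *_ = np.linalg.lstsq(design, responses, rcond=None)
    amplitude = math.hypot(s, c)
    fitted = design @ np.array([s, c])
    scale = max(amplitude, 1e-300)
    residual = float(np.sqrt(np.mean((responses - fitted) ** 2))) / scale
    if amplitude > 1e-9 and residual >= max_residual:
        raise ValueError(
            f"phase-sweep fit residual {residual:g} exceeds {max_residual:g}; "
            "measurement rejected"
        )
    return EmpiricalAmplitude(
        amplitude=amplitude, phase_offset=math.atan2(c, s), fit_residual=residual
    )


def argmax_frequency(
    amplitude_fn, theta: float, bracket: tuple[float, float] = (1e-3, 20.0)
) -> float:
    """Numeric argmax over omega of amplitude_fn(omega, theta).

    Assumes unimodality in omega (true for all the Gaussian-derivative
    amplitudes); golden-section/parabolic refinement to relative 1e-6.
    """
    lo, hi = bracket
    # coarse log-grid scan to localize the peak (the amplitude decays to a
    # flat exponential tail where local search would stall), then refine
    ws = np.geomspace(lo, hi, 201)
    vals = np.array([amplitude_fn(w, theta) for w in ws])
    i = int(np.argmax(vals))
    if vals[i] <= 0:
        raise ValueError("amplitude is zero on the whole bracket")
    if i in (0, len(ws) - 1):
        raise ValueError(f"argmax {ws[i]:g} at the edge of the bracket {bracket}")
    res = optimize.minimize_scalar(
        lambda w: -amplitude_fn(w, theta),
        bounds=(ws[i - 1], ws[i + 1]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def argmax_frequency_velocity(
    amplitude_fn,
    theta: float,
    omega_bracket: tuple[float, float] = (1e-3, 20.0),
    u_bracket: tuple[float, float] = (-10.0, 10.0),
    n_scan: int = 41,
) -> tuple[float, float]:
    """Joint numeric argmax over (omega, u): coarse grid scan, then local
    Nelder-Mead refinement."""
    omegas = np.geomspace(omega_bracket[0], omega_bracket[1], n_scan)
    us = np.linspace(u_bracket[0], u_bracket[1], n_scan)
    best = None
    for w in omegas:
        for u in us:
            val = amplitude_fn(w, u, theta)
            if best is None or val > best[0]:
                best = (val, w, u)
    if best is None or best[0] <= 0:
        raise ValueError("flat amplitude surface: no interior maximum found")
    res = optimize.minimize(
        lambda p: -amplitude_fn(p[0], p[1], theta),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
    )
    return float(res.x[0]), float(res.x[1])


def quadrature(fn, a: float, b: float, tol: float = 1e-10) -> float:
    """Adaptive quadrature to absolute tolerance tol."""
    val, err = integrate.quad(fn, a, b, epsabs=tol, epsrel=tol, limit=400)
    if err > 100 * max(tol, abs(val) * tol):
        raise ValueError(f"quadrature did not converge: estimated error {err:g}")
    return val


def find_root(fn, bracket: tuple[float, float], tol: float = 1e-10) -> float:
    """Bracketed root to absolute tolerance tol."""
    return float(optimize.brentq(fn, bracket[0], bracket[1], xtol=tol))
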