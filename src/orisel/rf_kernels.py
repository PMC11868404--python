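"""Receptive-field kernels: affine Gaussians, their scale-normalized
directional derivatives, spatio-temporal variants, and the Fourier transform
of the time-causal limit kernel.

The spatial kernels are m-th order directional derivatives along the
preferred orientation phi of an anisotropic (affine) Gaussian with
covariance Sigma_phi, multiplied by sigma1^m (scale normalization with
gamma = 1). Closed forms are used throughout; a generic orientation is
evaluated by rotating coordinates into the phi = 0 frame, which is exact by
rotation covariance of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import SpatialRFParams, SpatioTemporalRFParams, STMode

__all__ = [
    "CovarianceMatrix",
    "RasterGrid",
    "make_covariance",
    "eval_affine_gaussian",
    "eval_spatial_rf",
    "eval_temporal_kernel",
    "eval_spatiotemporal_rf",
    "limit_kernel_fourier",
    "make_grid",
    "discretize_rf",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class CovarianceMatrix:
    """Symmetric positive-definite 2x2 spatial covariance (length^2 units)."""

    C11: float
    C12: float
    C22: float

    def __post_init__(self) -> None:
        if self.C11 <= 0 or self.C22 <= 0 or self.det <= 0:
            raise ValueError("covariance matrix must be positive definite")

    @property
    def det(self) -> float:
        return self.C11 * self.C22 - self.C12 * self.C12

    def as_array(self) -> np.ndarray:
        return np.array([[self.C11, self.C12], [self.C12, self.C22]])


@dataclass(frozen=True)
class RasterGrid:
    """Uniformly sampled values on a 2-D (x1, x2) or 2+1-D (x1, x2, t) grid.

    ``axes`` holds the 1-D coordinate arrays; ``values`` (if present) has
    shape (len(x1), len(x2)[, len(t)]).
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def steps(self) -> tuple[float, ...]:
        return tuple(float(a[1] - a[0]) for a in self.axes)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.steps))

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        return np.meshgrid(*self.axes, indexing="ij")

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.axes, np.asarray(values))

    def integral(self) -> float:
        if self.values is None:
            raise ValueError("raster has no sampled values")
        return float(self.values.sum() * self.cell_volume)


def make_covariance(sigma1: float, sigma2: float, phi: float) -> CovarianceMatrix:
    """Spatial covariance with eigenvalues sigma1^2 (along phi), sigma2^2.

    C11 = s1^2 cos^2(phi) + s2^2 sin^2(phi)
    C12 = (s1^2 - s2^2) cos(phi) sin(phi)
    C22 = s1^2 sin^2(phi) + s2^2 cos^2(phi)
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("scales must be positive")
    s1, s2 = sigma1 * sigma1, sigma2 * sigma2
    c, s = math.cos(phi), math.sin(phi)
    return CovarianceMatrix(
        C11=s1 * c * c + s2 * s * s,
        C12=(s1 - s2) * c * s,
        C22=s1 * s * s + s2 * c * c,
    )


def eval_affine_gaussian(x1, x2, Sigma: CovarianceMatrix):
    """2-D affine Gaussian density with covariance Sigma.

    g(x) = exp(-x^T Sigma^{-1} x / 2) / (2 pi sqrt(det Sigma)).
    """
    det = Sigma.det
    if det <= 0:
        raise ValueError("singular covariance matrix")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    # inverse of [[C11, C12], [C12, C22]] scaled by 1/det
    q = (Sigma.C22 * x1 * x1 - 2.0 * Sigma.C12 * x1 * x2 + Sigma.C11 * x2 * x2) / det
    return np.exp(-0.5 * q) / (_TWO_PI * math.sqrt(det))


def _rotate_to_rf_frame(x1, x2, phi: float):
    """Coordinates in the frame where the preferred orientation is x1."""
    c, s = math.cos(phi), math.sin(phi)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return c * x1 + s * x2, -s * x1 + c * x2


def _spatial_rf_aligned(u, w, sigma1: float, sigma2: float, m: int):
    """phi = 0 closed forms of sigma1^m d^m/du^m of the separable Gaussian."""
    g = np.exp(-u * u / (2 * sigma1**2) - w * w / (2 * sigma2**2))
    if m == 0:
        return g / (_TWO_PI * sigma1 * sigma2)
    if m == 1:
        return -u * g / (_TWO_PI * sigma1**2 * sigma2)
    # m == 2
    return (u * u - sigma1**2) * g / (_TWO_PI * sigma1**3 * sigma2)


def eval_spatial_rf(x1, x2, p: SpatialRFParams):
    """Scale-normalized directional derivative of an affine Gaussian.

    Returns sigma1^m * d_phi^m g(x; Sigma_phi). Odd along phi for m = 1,
    even for m = 2; m = 0 coincides with :func:`eval_affine_gaussian`.
    """
    u, w = _rotate_to_rf_frame(x1, x2, p.phi)
    return _spatial_rf_aligned(u, w, p.sigma1, p.sigma2, p.m)


def eval_temporal_kernel(t, sigma_t: float, n: int = 0):
    """Scale-normalized derivative of the non-causal temporal Gaussian.

    sigma_t^n d^n/dt^n of h(t; sigma_t) = exp(-t^2/2 sigma_t^2)/(sqrt(2 pi) sigma_t).
    """
    t = np.asarray(t, dtype=float)
    h = np.exp(-t * t / (2 * sigma_t**2)) / (math.sqrt(_TWO_PI) * sigma_t)
    if n == 0:
        return h
    if n == 1:
        return -t * h / sigma_t
    if n == 2:
        return (t * t / sigma_t**2 - 1.0) * h
    raise ValueError(f"temporal order n={n} not in {{0,1,2}}")


def eval_spatiotemporal_rf(
    x1, x2, t, p: SpatioTemporalRFParams, *, allow_velocity_derivative: bool = False
):
    """Spatio-temporal receptive-field kernel.

    Separable mode: product of the spatial derivative kernel and a temporal
    Gaussian-derivative kernel. Velocity-adapted mode: the spatial kernel
    evaluated at (x1 - v t, x2) times the temporal Gaussian; the analysis of
    velocity-adapted probing holds for temporal order n = 0, so n > 0 is
    rejected unless ``allow_velocity_derivative`` is set.
    """
    sp = p.spatial
    if p.mode is STMode.VELOCITY_ADAPTED:
        if p.n != 0 and not allow_velocity_derivative:
            raise ValueError(
                "velocity-adapted kernels are analyzed for temporal order "
                "n = 0; pass allow_velocity_derivative=True to override"
            )
        t = np.asarray(t, dtype=float)
        spatial = eval_spatial_rf(
            np.asarray(x1, dtype=float) - p.v * t, x2, sp
        )
        return spatial * eval_temporal_kernel(t, p.sigma_t, p.n)
    return eval_spatial_rf(x1, x2, sp) * eval_temporal_kernel(t, p.sigma_t, p.n)


def limit_kernel_fourier(omega_t, sigma_t: float, c: float, K: int = 200):
    """Fourier transform of the time-causal limit kernel, truncated product.

    prod_{k=1..K} 1 / (1 + i c^{-k} sqrt(c^2-1) sigma_t omega_t).

    The infinite cascade of first-order integrators has geometrically
    decaying time constants, so the truncated product converges fast; the
    default K = 200 is far beyond 1e-10 relative accuracy for c >= sqrt(2).
    """
    if c <= 1:
        raise ValueError(f"distribution parameter c must exceed 1, got {c}")
    if K < 1:
        raise ValueError("truncation order K must be at least 1")
    omega_t = np.asarray(omega_t, dtype=float)
    gain = np.ones(np.shape(omega_t), dtype=complex)
    root = math.sqrt(c * c - 1.0)
    for k in range(1, K + 1):
        gain = gain / (1.0 + 1j * c ** (-k) * root * sigma_t * omega_t)
    return gain if gain.shape else complex(gain)


def make_grid(
    extents: tuple[tuple[float, float], ...], steps: tuple[float, ...]
) -> RasterGrid:
    """Uniform grid covering the given (lo, hi) extents, centered sampling."""
    axes = []
    for (lo, hi), h in zip(extents, steps):
        n = int(round((hi - lo) / h))
        axes.append(lo + h * np.arange(n + 1))
    return RasterGrid(tuple(axes))


def default_grid(
    p: SpatialRFParams | SpatioTemporalRFParams,
    n_sigma: float = 5.0,
    steps_per_sigma: float = 8.0,
) -> RasterGrid:
    """Grid covering +-n_sigma of the kernel with step min(sigma)/steps_per_sigma."""
    if isinstance(p, SpatioTemporalRFParams):
        sp = p.spatial
        reach = n_sigma * sp.sigma1 + abs(p.velocity) * n_sigma * p.sigma_t
        h = min(sp.sigma1, sp.sigma2, p.sigma_t) / steps_per_sigma
        return make_grid(
            (
                (-reach, reach),
                (-n_sigma * sp.sigma2, n_sigma * sp.sigma2),
                (-n_sigma * p.sigma_t, n_sigma * p.sigma_t),
            ),
            (h, h, h),
        )
    smax = max(p.sigma1, p.sigma2)
    h = min(p.sigma1, p.sigma2) / steps_per_sigma
    # generic phi mixes the axes, so cover the larger scale in both
    if p.phi % math.pi == 0.0:
        e1, e2 = n_sigma * p.sigma1, n_sigma * p.sigma2
    else:
        e1 = e2 = n_sigma * smax
    return make_grid(((-e1, e1), (-e2, e2)), (h, h))


def discretize_rf(
    p: SpatialRFParams | SpatioTemporalRFParams, grid: RasterGrid | None = None
) -> RasterGrid:
    """Sample the kernel on a grid, checking resolution and coverage.

    The grid must cover at least +-5 standard deviations per axis and resolve
    the finest scale with step <= min(sigma)/4; violations raise with the
    violated bound, since an under-resolved raster silently biases the
    empirical amplitudes measured from it.
    """
    if grid is None:
        grid = default_grid(p)
    if isinstance(p, SpatioTemporalRFParams):
        sigmas = (p.spatial.sigma1, p.spatial.sigma2, p.sigma_t)
    else:
        sigmas = (p.sigma1, p.sigma2)
    if grid.ndim != len(sigmas):
        raise ValueError(f"grid dimension {grid.ndim} != kernel dimension {len(sigmas)}")
    max_step = min(sigmas) / 4.0
    for ax, h, s in zip(grid.axes, grid.steps, sigmas):
        if h > max_step * (1 + 1e-12):
            raise ValueError(
                f"grid step {h:g} exceeds resolution bound min(sigma)/4 = {max_step:g}"
            )
        if ax[0] > -5 * s or ax[-1] < 5 * s:
            raise ValueError(
                f"grid extent [{ax[0]:g}, {ax[-1]:g}] does not cover +-5 sigma = "
                f"+-{5 * s:g}"
            )
    mesh = grid.meshgrid()
    if isinstance(p, SpatioTemporalRFParams):
        values = eval_spatiotemporal_rf(*mesh, p)
    else:
        values = eval_spatial_rf(*mesh, p)
    return grid.with_values(values)
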