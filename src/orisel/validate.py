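"""Self-validation: oracle-vs-closed-form check families.

Each check family recomputes a closed-form result by an independent route
(rendered rasters, numeric argmax, quadrature, root-finding) and reports
the achieved worst-case deviation against its tolerance. Used by the
``orisel validate`` command and by the acceptance machinery.
"""

from __future__ import annotations

import math

import numpy as np

from .gabor_model import (
    discretize_gabor,
    gabor_amplitudes,
    gabor_energy,
    gabor_energy_from_responses,
)
from .numeric_oracle import (
    argmax_frequency,
    argmax_frequency_velocity,
    empirical_amplitude,
)
from .params import (
    GaborParams,
    QuadratureConfig,
    SineProbe,
    SpatialRFParams,
    SpatioTemporalRFParams,
    STMode,
)
from .probe_response import (
    optimal_frequency,
    optimal_velocity,
    spatial_amplitude,
    st_amplitude,
    st_optimal_frequency,
)
from .rf_kernels import discretize_rf
from .tuning_curves import (
    default_thetas,
    lambda_scaled_curve,
    quadrature_curve_from_amplitudes,
    canonical_curve,
    velocity_mismatch_curve,
    velocity_mismatch_curve_from_amplitudes,
)
from .tuning_measures import (
    bandwidth,
    closed_form_bandwidth,
    closed_form_resultant,
    lambda_resultant_simple1,
    resultant,
)

THETA_GRID = (0.0, math.pi / 8, math.pi / 4, 3 * math.pi / 8)
KAPPA_GRID = (1.0, 2.0, 4.0, 8.0)


def check_amplitude_oracle(
    kappas=KAPPA_GRID, thetas=THETA_GRID, omegas=("0.5", "opt", "2")
) -> dict:
    """Rendered-grating amplitudes vs the closed forms (rel. tol 1e-3).

    Rasters extend to +-8 sigma so the domain-truncation error stays far
    below the amplitudes being compared; responses below an absolute floor
    of 1e-6 (analytic near-zeros, where a relative comparison is
    meaningless) are compared absolutely against that floor.
    """
    from .rf_kernels import default_grid

    floor = 1e-6
    worst = 0.0
    n = 0
    for m in (1, 2):
        for kappa in kappas:
            p = SpatialRFParams(1.0, kappa, m=m)
            raster = discretize_rf(p, default_grid(p, n_sigma=8.0))
            for theta in thetas:
                for wspec in omegas:
                    if wspec == "opt":
                        model = "simple1" if m == 1 else "simple2"
                        w = float(optimal_frequency(1.0, kappa, theta, model))
                    else:
                        w = float(wspec)
                    probe = SineProbe(w, theta)
                    closed = spatial_amplitude(p, probe).amplitude
                    measured = empirical_amplitude(raster, probe).amplitude
                    worst = max(worst, abs(measured - closed) / max(closed, floor))
                    n += 1
    return {"max_rel_error": worst, "n": n, "tol": 1e-3, "passed": worst < 1e-3}


def check_optimal_probe_recovery(kappas=KAPPA_GRID, thetas=THETA_GRID) -> dict:
    """Numeric argmax over omega (and jointly over (omega, u)) vs closed forms."""
    worst = 0.0
    n = 0
    for m, model in ((1, "simple1"), (2, "simple2")):
        p = SpatialRFParams(1.0, 1.0, m=m)
        for kappa in kappas:
            pk = SpatialRFParams(1.0, kappa, m=m)
            for theta in thetas:
                closed = float(optimal_frequency(1.0, kappa, theta, model))

                def amp(w, th, _p=pk):
                    return spatial_amplitude(_p, SineProbe(w, th)).amplitude

                numeric = argmax_frequency(amp, theta)
                worst = max(worst, abs(numeric - closed) / closed)
                n += 1
    # joint (omega, u) recovery for velocity-adapted amplitudes
    for m, model in ((1, "simple1"), (2, "simple2")):
        for kappa in (1.0, 2.0):
            for v in (0.5, 2.0):
                sp = SpatialRFParams(1.0, kappa, m=m)
                p = SpatioTemporalRFParams(
                    sp, 1.0, v=v, n=0, mode=STMode.VELOCITY_ADAPTED
                )
                for theta in (0.0, math.pi / 3):
                    def amp(w, u, th, _p=p):
                        return st_amplitude(_p, SineProbe(w, th, u=u)).amplitude

                    w_num, u_num = argmax_frequency_velocity(amp, theta)
                    w_cl = float(st_optimal_frequency(p, theta, model))
                    u_cl = float(optimal_velocity(p, theta))
                    worst = max(worst, abs(w_num - w_cl) / w_cl)
                    scale = max(abs(u_cl), 1.0)
                    worst = max(worst, abs(u_num - u_cl) / scale)
                    n += 1
    return {"max_rel_error": worst, "n": n, "tol": 1e-4, "passed": worst < 1e-4}


def check_canonical_equivalence(
    kappas=KAPPA_GRID, n_theta: int = 181, cfg: QuadratureConfig | None = None
) -> dict:
    """Quasi-quadrature and simple-cell constructions vs the canonical curves."""
    if cfg is None:
        cfg = QuadratureConfig()
    thetas = default_thetas(n_theta)
    worst = 0.0
    for kappa in kappas:
        for rf_class in ("spatial", "velocity_adapted"):
            rebuilt = quadrature_curve_from_amplitudes(rf_class, kappa, thetas, cfg)
            canonical = canonical_curve("complex", rf_class, kappa, thetas)
            worst = max(worst, float(np.max(np.abs(rebuilt - canonical))))
        for model in ("simple1", "simple2"):
            rebuilt = lambda_scaled_curve(model, kappa, 1.0, thetas)
            canonical = canonical_curve(model, "spatial", kappa, thetas)
            worst = max(worst, float(np.max(np.abs(rebuilt - canonical))))
    return {"max_abs_error": worst, "n": len(kappas) * 4 * n_theta,
            "tol": 1e-10, "passed": worst < 1e-10}


def check_resultant_closed_forms(kappas=(1.5, 2.0, 4.0, 8.0)) -> dict:
    """Quadrature resultants vs the arccosh and kappa/(kappa+1) forms."""
    worst = 0.0
    for kappa in kappas:
        for model in ("simple1", "simple2"):
            quad = resultant(lambda t: canonical_curve(model, "spatial", kappa, t))
            closed = closed_form_resultant(model, kappa)
            worst = max(worst, abs(quad - closed))
    quad1 = resultant(lambda t: canonical_curve("simple1", "spatial", 1.0, t))
    worst = max(worst, abs(quad1 - 1.0 / 3.0))
    return {"max_abs_error": worst, "n": 2 * len(kappas) + 1,
            "tol": 1e-8, "passed": worst < 1e-8}


def check_bandwidth_closed_forms(kappas=(1.0, 1.5, 2.0, 4.0, 8.0)) -> dict:
    """Root-found bandwidths vs the closed forms."""
    worst = 0.0
    for kappa in kappas:
        for model in ("simple1", "simple2"):
            b_num, _ = bandwidth(lambda t: canonical_curve(model, "spatial", kappa, t))
            worst = max(worst, abs(b_num - closed_form_bandwidth(model, kappa)))
    return {"max_abs_error": worst, "n": 2 * len(kappas),
            "tol": 1e-8, "passed": worst < 1e-8}


def check_lambda_invariance(
    kappas=(2.0, 4.0), lambdas=(0.5, 1.0, 3.0), n_theta: int = 181
) -> dict:
    """Normalized lambda-scaled curves are identical for all lambda."""
    thetas = default_thetas(n_theta)
    worst = 0.0
    for model in ("simple1", "simple2"):
        for kappa in kappas:
            ref = lambda_scaled_curve(model, kappa, 1.0, thetas)
            for lam in lambdas:
                cur = lambda_scaled_curve(model, kappa, lam, thetas)
                worst = max(worst, float(np.max(np.abs(cur - ref))))
    return {"max_abs_error": worst, "n": len(kappas) * len(lambdas) * 2,
            "tol": 1e-12, "passed": worst < 1e-12}


def check_velocity_mismatch_reduction(n_theta: int = 181) -> dict:
    """mu = 1 reproduces the canonical curves; mu != 1 matches the direct
    amplitude route through the effective kappa_tilde."""
    thetas = default_thetas(n_theta)
    worst = 0.0
    for model in ("simple1", "simple2"):
        mu1 = velocity_mismatch_curve(model, 2.0, 1.0, 1.0, 1.0, 1.0, thetas)
        worst = max(
            worst,
            float(np.max(np.abs(mu1 - canonical_curve(model, "spatial", 2.0, thetas)))),
        )
        reduced = velocity_mismatch_curve(model, 2.0, 2.0, 1.0, 1.0, 1.0, thetas)
        direct = velocity_mismatch_curve_from_amplitudes(
            model, 2.0, 2.0, 1.0, 1.0, 1.0, thetas
        )
        worst = max(worst, float(np.max(np.abs(reduced - direct))))
    return {"max_abs_error": worst, "n": 4 * n_theta, "tol": 1e-10,
            "passed": worst < 1e-10}


def check_gabor_routes(n_points: int = 100, seed: int = 0) -> dict:
    """Energy route equivalence at random points and raster-oracle
    agreement with the Gabor amplitudes."""
    rng = np.random.default_rng(seed)
    worst_route = 0.0
    pts = rng.uniform(-3, 3, size=(n_points, 2))
    thetas = rng.uniform(-math.pi / 2, math.pi / 2, size=n_points)
    betas = rng.uniform(0, 2 * math.pi, size=n_points)
    for (x1, x2), th, beta in zip(pts, thetas, betas):
        e1 = gabor_energy(x1, x2, th, 1.0, 2.0, 1.0, beta)
        e2 = gabor_energy_from_responses(x1, x2, th, 1.0, 2.0, 1.0, beta)
        worst_route = max(worst_route, abs(float(e1) - float(e2)))
    worst_amp = 0.0
    for kappa in (1.0, 2.0):
        for parity in ("even", "odd"):
            raster = discretize_gabor(1.0, kappa, 1.0, parity)
            for theta in (0.0, math.pi / 4):
                a_e, a_o = gabor_amplitudes(theta, 1.0, kappa, 1.0)
                closed = a_e if parity == "even" else a_o
                measured = empirical_amplitude(
                    raster, SineProbe(1.0, theta)
                ).amplitude
                if closed > 1e-9:
                    worst_amp = max(worst_amp, abs(measured - closed) / closed)
    return {
        "max_route_error": worst_route,
        "max_amp_rel_error": worst_amp,
        "n": n_points,
        "tol_route": 1e-12,
        "tol_amp": 1e-3,
        "passed": worst_route < 1e-12 and worst_amp < 1e-3,
    }


CHECK_FAMILIES = {
    "amplitude_oracle": check_amplitude_oracle,
    "optimal_probe_recovery": check_optimal_probe_recovery,
    "canonical_equivalence": check_canonical_equivalence,
    "resultant_closed_forms": check_resultant_closed_forms,
    "bandwidth_closed_forms": check_bandwidth_closed_forms,
    "lambda_invariance": check_lambda_invariance,
    "velocity_mismatch_reduction": check_velocity_mismatch_reduction,
    "gabor_routes": check_gabor_routes,
}


def run_validation(families=None) -> dict:
    """Run the requested check families (all by default)."""
    names = list(CHECK_FAMILIES) if families is None else list(families)
    report = {}
    for name in names:
        report[name] = CHECK_FAMILIES[name]()
    report["all_passed"] = all(report[name]["passed"] for name in names)
    return report
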