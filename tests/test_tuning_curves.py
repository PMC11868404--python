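"""Orientation-selectivity curves: canonical forms, the quasi-quadrature
reconstruction, probe-mismatch variants, and their invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orisel.numeric_oracle import argmax_frequency, empirical_amplitude
from orisel.params import QuadratureConfig, SineProbe, SpatialRFParams
from orisel.rf_kernels import default_grid, discretize_rf
from orisel.tuning_curves import (
    default_thetas,
    effective_kappa,
    fixed_frequency_and_velocity_curve,
    fixed_frequency_curve,
    lambda_scaled_curve,
    quadrature_curve_from_amplitudes,
    sample_curve,
    canonical_curve,
    velocity_mismatch_curve,
    velocity_mismatch_curve_from_amplitudes,
)

THETAS = default_thetas()
KAPPAS = (1.0, 2.0, 4.0, 8.0)


class TestCanonicalCurve:
    @pytest.mark.parametrize("model", ["simple1", "simple2", "complex"])
    @pytest.mark.parametrize("rf_class", ["spatial", "separable", "velocity_adapted"])
    @pytest.mark.parametrize("kappa", KAPPAS)
    def test_normalized_symmetric_bounded(self, model, rf_class, kappa):
        vals = canonical_curve(model, rf_class, kappa, THETAS)
        assert vals[len(THETAS) // 2] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(vals, vals[::-1], atol=1e-12)
        assert np.all((vals >= -1e-15) & (vals <= 1 + 1e-12))

    def test_simple2_example(self):
        assert canonical_curve("simple2", "spatial", 2.0, math.pi / 4) == pytest.approx(
            0.2, rel=1e-12
        )

    def test_simple1_example(self):
        assert canonical_curve("simple1", "spatial", 2.0, math.pi / 4) == pytest.approx(
            1 / math.sqrt(5), rel=1e-12
        )

    def test_complex_separable_peak_normalized(self):
        # the raw separable complex form evaluates to 2 at theta = 0
        for kappa in KAPPAS:
            assert canonical_curve("complex", "separable", kappa, 0.0) == pytest.approx(
                1.0, abs=1e-14
            )

    def test_monotone_narrowing_in_kappa(self):
        """At any interior orientation the curve strictly decreases with
        kappa, for every model and receptive-field class."""
        for model in ("simple1", "simple2", "complex"):
            for rf_class in ("spatial", "separable", "velocity_adapted"):
                for theta in (0.3, 0.8, 1.2):
                    vals = [
                        float(canonical_curve(model, rf_class, k, theta)) for k in KAPPAS
                    ]
                    assert np.all(np.diff(vals) < 0), (model, rf_class, theta)

    def test_second_order_narrower_than_first(self):
        for kappa in (2.0, 4.0, 8.0):
            for theta in (0.3, 0.8, 1.2):
                s1 = canonical_curve("simple1", "spatial", kappa, theta)
                s2 = canonical_curve("simple2", "spatial", kappa, theta)
                assert s2 <= s1 + 1e-15

    def test_unknown_enums_rejected(self):
        with pytest.raises(ValueError):
            canonical_curve("simple3", "spatial", 1.0, 0.0)
        with pytest.raises(ValueError):
            canonical_curve("simple1", "temporal", 1.0, 0.0)

    def test_kappa_below_one_warns(self):
        with pytest.warns(UserWarning):
            canonical_curve("simple1", "spatial", 0.5, 0.3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        kappa=st.floats(1.0, 10.0),
        theta=st.floats(-math.pi / 2, math.pi / 2),
        model=st.sampled_from(["simple1", "simple2", "complex"]),
    )
    def test_symmetry_and_bounds_property(self, kappa, theta, model):
        v = float(canonical_curve(model, "spatial", kappa, theta))
        v_neg = float(canonical_curve(model, "spatial", kappa, -theta))
        assert v == pytest.approx(v_neg, abs=1e-12)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestQuadratureCurve:
    @pytest.mark.parametrize("rf_class", ["spatial", "velocity_adapted"])
    @pytest.mark.parametrize("kappa", KAPPAS)
    def test_equals_canonical_complex_curve(self, rf_class, kappa):
        rebuilt = quadrature_curve_from_amplitudes(rf_class, kappa, THETAS)
        canonical = canonical_curve("complex", rf_class, kappa, THETAS)
        assert np.max(np.abs(rebuilt - canonical)) < 1e-10

    def test_isotropic_case_is_cos_three_halves(self):
        rebuilt = quadrature_curve_from_amplitudes("spatial", 1.0, THETAS)
        assert np.max(np.abs(rebuilt - np.abs(np.cos(THETAS)) ** 1.5)) < 1e-12

    def test_kappa2_value(self):
        val = quadrature_curve_from_amplitudes("spatial", 2.0, math.pi / 4)
        expected = (1 / math.sqrt(2)) ** 1.5 / 2.5**0.75
        assert val == pytest.approx(expected, rel=1e-12)

    def test_weight_cancels_from_normalized_curve(self):
        """C_phi scales the energy by the constant factor C^{1/4}, so the
        peak-normalized curve is weight-independent ..."""
        alt = quadrature_curve_from_amplitudes(
            "spatial", 2.0, THETAS, QuadratureConfig(C_phi=1.0)
        )
        canonical = canonical_curve("complex", "spatial", 2.0, THETAS)
        assert np.max(np.abs(alt - canonical)) < 1e-10

    def test_raw_peak_sensitive_to_quadrature_weight(self):
        """... but the raw peak amplitude is C-sensitive: it equals
        2^{1/4} e^{-1/sqrt 2} only at C_phi = 1/sqrt 2 (corruption control)."""
        from orisel.params import SineProbe, SpatialRFParams
        from orisel.probe_response import spatial_amplitude
        from orisel.tuning_curves import raw_peak_amplitude

        omega_q = 2.0**0.25
        a1 = spatial_amplitude(SpatialRFParams(1, 2, m=1), SineProbe(omega_q)).amplitude
        a2 = spatial_amplitude(SpatialRFParams(1, 2, m=2), SineProbe(omega_q)).amplitude

        def raw_peak(c_phi):
            return math.sqrt(a1 * math.sqrt(c_phi) * a2)

        assert raw_peak(1 / math.sqrt(2)) == pytest.approx(
            raw_peak_amplitude("complex"), rel=1e-12
        )
        assert abs(raw_peak(1.0) - raw_peak_amplitude("complex")) > 1e-2


class TestLambdaScaledCurve:
    def test_lambda_one_is_canonical(self):
        for model in ("simple1", "simple2"):
            vals = lambda_scaled_curve(model, 4.0, 1.0, THETAS)
            assert np.max(
                np.abs(vals - canonical_curve(model, "spatial", 4.0, THETAS))
            ) < 1e-12

    @pytest.mark.parametrize("lam", [0.5, 3.0])
    def test_lambda_invariance(self, lam):
        for model in ("simple1", "simple2"):
            ref = lambda_scaled_curve(model, 4.0, 1.0, THETAS)
            cur = lambda_scaled_curve(model, 4.0, lam, THETAS)
            assert np.max(np.abs(cur - ref)) < 1e-12

    def test_half_lambda_example(self):
        assert lambda_scaled_curve("simple2", 2.0, 0.5, math.pi / 4) == pytest.approx(
            0.2, rel=1e-10
        )

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            lambda_scaled_curve("simple1", 2.0, 0.0, 0.3)


class TestFixedFrequencyCurve:
    def test_peak_normalized(self):
        for model in ("simple1", "simple2", "complex"):
            assert fixed_frequency_curve(model, 2.0, 1.0, 0.0) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_isotropic_first_order_is_cosine(self):
        for lam in (0.5, 1.0, 2.0):
            vals = fixed_frequency_curve("simple1", 1.0, lam, THETAS)
            assert np.max(np.abs(vals - np.abs(np.cos(THETAS)))) < 1e-12

    def test_second_order_example(self):
        val = fixed_frequency_curve("simple2", 2.0, 1.0, math.pi / 4)
        assert val == pytest.approx(math.exp(-1.5) * 0.5, rel=1e-12)

    @pytest.mark.parametrize("model", ["simple1", "simple2"])
    @pytest.mark.parametrize("kappa", [2.0, 4.0, 8.0])
    def test_narrower_than_adapted_probing(self, model, kappa):
        """The simple-cell fixed-frequency curves carry an extra
        exp(-(k^2-1) l^2 sin^2 ...) <= 1 factor, so they sit pointwise below
        the adapted-probe curves (the complex-cell construction has no such
        closed-form bound and can exceed the adapted curve marginally near
        the peak)."""
        fixed = fixed_frequency_curve(model, kappa, 1.0, THETAS)
        adapted = canonical_curve(model, "spatial", kappa, THETAS)
        assert np.all(fixed <= adapted + 1e-12)


class TestVelocityMismatchCurve:
    def test_mu_one_reduces_to_canonical(self):
        for model in ("simple1", "simple2"):
            vals = velocity_mismatch_curve(model, 2.0, 1.0, 1.0, 1.0, 1.0, THETAS)
            assert np.max(
                np.abs(vals - canonical_curve(model, "spatial", 2.0, THETAS))
            ) < 1e-14

    def test_effective_kappa_example(self):
        assert effective_kappa(2.0, 2.0, 1.0, 1.0, 1.0) == pytest.approx(
            math.sqrt(2), rel=1e-12
        )

    def test_mismatch_curve_value(self):
        val = velocity_mismatch_curve("simple2", 2.0, 2.0, 1.0, 1.0, 1.0, math.pi / 4)
        assert val == pytest.approx(1.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("model", ["simple1", "simple2"])
    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0])
    def test_matches_direct_amplitude_route(self, model, lam):
        reduced = velocity_mismatch_curve(model, 2.0, 2.0, 1.0, 1.0, 1.0, THETAS)
        direct = velocity_mismatch_curve_from_amplitudes(
            model, 2.0, 2.0, 1.0, 1.0, 1.0, THETAS, lam=lam
        )
        assert np.max(np.abs(reduced - direct)) < 1e-10


class TestFixedFrequencyAndVelocityCurve:
    def test_peak_normalized(self):
        assert fixed_frequency_and_velocity_curve(
            "simple1", 2.0, 1.0, 2.0, 1.0, 1.0, 1.0, 0.0
        ) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 3.0])
    def test_zero_velocity_reduces_to_fixed_frequency(self, mu):
        for model in ("simple1", "simple2"):
            vals = fixed_frequency_and_velocity_curve(
                model, 2.0, 1.0, mu, 1.0, 1.0, 0.0, THETAS
            )
            expected = fixed_frequency_curve(model, 2.0, 1.0, THETAS)
            assert np.max(np.abs(vals - expected)) < 1e-12

    def test_two_evaluation_routes_agree(self):
        """The curve built through the amplitude formula equals a direct
        re-substitution of the probe parameters into the exponent."""
        kappa, lam, mu, s1, st_, v = 2.0, 1.0, 1.0, 1.0, 1.0, 1.0
        omega = lam / math.sqrt((mu - 1) ** 2 * st_**2 * v**2 + s1**2)
        u = mu * v
        thetas = np.linspace(-1.2, 1.2, 41)

        def direct(th):
            expo = -0.5 * omega**2 * (
                (s1**2 + st_**2 * v**2) * math.cos(th) ** 2
                + (kappa * s1) ** 2 * math.sin(th) ** 2
                - 2 * st_**2 * u * v * math.cos(th)
                + st_**2 * u**2
            )
            return omega * s1 * abs(math.cos(th)) * math.exp(expo)

        direct_vals = np.array([direct(t) for t in thetas]) / direct(0.0)
        vals = fixed_frequency_and_velocity_curve(
            "simple1", kappa, lam, mu, s1, st_, v, thetas
        )
        assert np.max(np.abs(vals - direct_vals)) < 1e-8


class TestSampleCurve:
    def test_metadata_and_invariants(self):
        curve = sample_curve("simple1", "spatial", 2.0)
        assert curve.model == "simple1"
        assert curve.values[len(curve.thetas) // 2] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(curve.values, curve.values[::-1], atol=1e-12)

    def test_interpolation_callable(self):
        curve = sample_curve("simple2", "spatial", 2.0)
        assert curve(math.pi / 4) == pytest.approx(0.2, abs=1e-3)

    def test_unknown_probing_rejected(self):
        with pytest.raises(ValueError):
            sample_curve("simple1", probing="adaptive")


class TestEndToEndOracle:
    @pytest.mark.parametrize("m,model", [(1, "simple1"), (2, "simple2")])
    def test_raster_measured_curve_matches_canonical(self, m, model):
        """Rendered gratings -> discretized kernel -> empirical amplitude ->
        per-orientation argmax reproduces the canonical curve."""
        kappa = 2.0
        p = SpatialRFParams(1.0, kappa, m=m)
        raster = discretize_rf(p, default_grid(p, n_sigma=8.0))
        thetas = (0.0, math.pi / 8, math.pi / 4, 3 * math.pi / 8)

        def amp(w, th):
            return empirical_amplitude(raster, SineProbe(w, th)).amplitude

        measured = []
        for th in thetas:
            w_hat = argmax_frequency(amp, th, bracket=(0.05, 5.0))
            measured.append(amp(w_hat, th))
        measured = np.array(measured) / measured[0]
        canonical = np.array(
            [canonical_curve(model, "spatial", kappa, th) for th in thetas]
        )
        assert np.max(np.abs(measured - canonical) / canonical) < 1e-3
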