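# Methods

## Model family and conventions

All receptive fields live in a coordinate frame where the preferred
orientation is φ, measured counter-clockwise from the x₁ axis; the analysis
aligns φ = 0 without loss of generality (rotation covariance of the affine
Gaussian family is exact and unit-tested). Probing gratings are
sin(ω(cos θ x₁ + sin θ x₂) + β), with inclination θ reported on
[−π/2, π/2], matching the convention of plotting tuning curves relative to
the preferred orientation. Velocities are scalars along φ; the moving
grating's phase is ω(cos θ x₁ + sin θ x₂ − u t) + β, so u is the image
velocity conjugate to the receptive-field velocity v.

The spatial covariance is parameterized by (σ₁, σ₂, φ) with eigenvalues
σ₁², σ₂²; the scale parameter ratio κ = σ₂/σ₁ ≥ 1 is the single shape
parameter that survives into every normalized tuning curve. Scale
normalization uses γ = 1 (σ₁^m prefactor), which makes the peak response
amplitude independent of σ₁ — the package rejects other γ values rather
than silently producing non-scale-invariant curves. The quasi-quadrature
weights default to C_φ = C_t = 1/√2 and the complementary normalization
power Γ is fixed at 0.

Temporal smoothing defaults to the non-causal Gaussian. The time-causal
limit kernel (an infinite cascade of first-order integrators with
geometrically decaying time constants, parameter c > 1) is exposed only
through its Fourier transform, truncated at K = 200 factors; since the
factors approach 1 geometrically, K = 200 is beyond 1e-10 relative accuracy
for c ≥ √2 (checked against K = 10K).

## Amplitudes and tuning curves

For a linear filter the response to a sine grating is a phase-shifted wave;
the "amplitude" is defined analytically as the prefactor of that response
wave (nonnegative, with the carrier class — cosine for odd-order, sine for
even-order filters — recorded separately), not as an empirical maximum.
The velocity-adapted spatio-temporal amplitude carries the exponent
−ω²/2 [(σ₁² + σ_t²v²)cos²θ + σ₂²sin²θ − 2σ_t²uv cos θ + σ_t²u²]; the
space-time separable amplitude is the product of the spatial amplitude and
(ω u σ_t)^n e^{−ω²u²σ_t²/2}, which follows from separability of the 3-D
convolution (the Fourier transform factorizes). The separable form is not
taken on trust: its normalized curves are checked against the canonical
table and the raster oracle.

Public tuning curves are peak-normalized to r(0) = 1. The raw θ = 0 peak
amplitudes (1/√e, 2/e, 2^{1/4}e^{−1/√2}) are exposed separately because
they carry the C_φ dependence: in the geometric-mean-of-extremes collapse
of the complex-cell energy, C_φ enters only as the constant factor
C_φ^{1/4} and cancels under peak normalization. The separable complex-cell
curve is divided by its raw θ = 0 value of 2 so that all returned curves
peak at 1.

The complex-cell phase ripple is collapsed by the geometric mean of the
extremes of Q(ψ) = √(A₁²cos²ψ + C_φ A₂²sin²ψ), i.e. √(A₁ √C_φ A₂). For the
complex-cell column of the canonical table, the independent quasi-quadrature
recomputation reproduces the |cos θ|^{3/2}/(cos²θ + κ²sin²θ)^{3/4} form to
machine precision, which is why that form (rather than variants with other
exponents) is treated as authoritative.

## Probe-mismatch protocols

- **λ-scaled adapted probing**: ω = λ ω̂(θ). The λ factor multiplies the
  amplitude by a θ-independent function, so the normalized curve is exactly
  λ-invariant; asserted to 1e-12.
- **Fixed-frequency probing**: ω fixed at λ times the θ = 0 optimum. The
  simple-cell curves acquire the extra factor e^{−(κ²−1)λ²sin²θ(·)} ≤ 1
  and therefore sit pointwise below the adapted curves; the first-order
  resultant has a closed form in erf, matched against quadrature to 1e-8.
  The complex-cell fixed-frequency curve is built numerically; it has no
  such pointwise bound and can exceed the adapted curve by ~1e-3 near the
  peak, because at the geometric-mean frequency the product A₁A₂ is still
  increasing in ω (its own optimum is at √(3/2)/(σ₁s), slightly above
  2^{1/4}/(σ₁s)).
- **Velocity mismatch**: u = μ v cos θ with the frequency re-optimized
  given that velocity, ω̂ = λ·numerator/√((σ₁² + (μ−1)²σ_t²v²)cos²θ +
  κ²σ₁²sin²θ). With this pairing the normalized curve is exactly the
  canonical simple-cell curve with κ replaced by
  κ̃ = κ/√(1 + (μ−1)²ṽ²), ṽ = σ_t v/σ₁, and is λ-independent; both
  properties are verified to machine precision against direct amplitude
  evaluation. Pairing the mismatched velocity with the *unperturbed*
  adapted frequency instead breaks both the reduction and the
  λ-independence (by ~0.16 in curve value at κ = μ = 2), so that pairing is
  not offered.
- **Fixed frequency and velocity**: ω and u frozen at their θ = 0 values
  (λ, μ scalings); evaluated numerically, reduces to the fixed-frequency
  spatial curve when v = 0.

## The affine Gabor model

The Gabor pair is probed at ω = ν without per-orientation frequency
adaptation (the optimum has no tractable closed form), so its selectivity
depends on κ *and* the dimensionless product σ₁ν. The implemented
amplitudes are the prefactors of the closed-form responses,

    A_even/odd(θ) = ½ (e^{2a cos θ} ± 1) e^{−a cos²(θ/2)[(κ²−1)(1−cos θ) + 2]},
    a = (σ₁ν)²,

equivalently cosh/sinh(a cos θ)·e^{−a}·e^{−(κ²−1)a sin²θ/2}. These are
derived independently in the Fourier domain (the filter transform is a
pair of shifted Gaussians) and verified against the rendered-raster oracle
to 1e-3 relative; the even/odd responses ride on sine/cosine carriers
respectively. The energy Q² is computed both as the expanded closed form
and as the sum of squared responses, and the two routes agree to 1e-12 at
random points. Because the ripple of Q never vanishes off the preferred
orientation, the energy tuning curve needs a collapse convention: the
spatial mean of Q over one carrier period is the default, with the
geometric mean of the extremes exported alongside.

## Numeric oracle

The oracle never reuses a closed form it checks. Stimuli are rendered on
uniform rasters (≥ 8 samples per carrier period per axis, enforced);
kernels are sampled on grids covering at least ±5σ per axis with step at
most min(σ)/4 (defaults ±5σ, σ/8; violations raise with the violated
bound). The response is evaluated at the grid center only — translation
invariance makes one point sufficient — for a sweep of 8 stimulus phases,
and the amplitude is read off a least-squares sinusoid fit, whose relative
RMS residual must stay below 1e-3 (for a linear chain it is at rounding
level). Oracle-grade comparisons use ±8σ rasters so that the
domain-truncation error (~e^{−32} of the kernel scale) sits far below the
1e-6 absolute floor applied where closed-form amplitudes are numerically
zero (deep in the Gaussian frequency tail a relative comparison is
meaningless at any raster precision). Frequency argmaxes use a 201-point
log-grid scan followed by bounded refinement (the amplitude surfaces are
unimodal but flatten to exponential tails where unguarded local search
stalls); joint (ω, u) argmaxes use a coarse scan plus Nelder–Mead.
Quadrature (scipy adaptive, abs tol 1e-10) and bracketed root-finding
(Brent, 1e-10) back the resultant and bandwidth; sampled curves are
integrated by the trapezoid rule on their own θ grid instead, since
adaptive quadrature on a piecewise-linear interpolant only chases
roundoff. Everything is deterministic.

## Problem sizes and defaults

The θ grid defaults to 181 uniform points on [−π/2, π/2]; κ defaults to
{1, 2, 4, 8} for curves and 57 points on [1, 8] for measure sweeps; the
Gabor grid is {1, 2, 4, 8} × {1/2, 1, 2} in (κ, σ₁ν). The full validation
suite — 96 raster amplitude measurements, 48 argmax recoveries, ~2.9k
curve-equivalence points, measure closed-form checks, invariance and
reduction checks, and 100-point Gabor route equivalence — runs in about a
second on one core.

## Known limitations

- Derivative orders are restricted to m ∈ {0, 1, 2} and n ∈ {0, 1, 2};
  higher orders are rejected.
- Velocity-adapted filters are analyzed at temporal order n = 0 (nonzero
  temporal differentiation of a velocity-matched filter responds to the
  mismatch, not the orientation); evaluation with n > 0 requires an
  explicit override and has no amplitude closed form here.
- Complex-cell resultants and bandwidths, and the second-order
  fixed-frequency resultant, have no closed forms in the package; they are
  defined by quadrature/root-finding with a two-tolerance self-consistency
  check instead of special-function (hypergeometric/Bessel) expressions.
- The time-causal temporal channel is evaluation-only (Fourier gain); no
  recursive-filter implementation or time-causal tuning analysis.
- Spatio-temporal Gabor models are excluded; there is no canonical way to
  pair the carrier with the temporal axis in this framework.
- All results are noise-free properties of idealized linear/energy models;
  nothing here fits neurophysiological data, and passing oracle checks
  says nothing about how well the models describe any particular neuron.
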