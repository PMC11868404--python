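# orisel — orientation selectivity of idealized V1 receptive-field models

`orisel` computes, in closed form and by independent numeric verification,
the orientation tuning of idealized models of simple and complex cells in
the primary visual cortex. It is aimed at computational neuroscientists who
want to compare measured orientation-selectivity curves, resultants,
circular variances or bandwidths against what the affine Gaussian
derivative and affine Gabor receptive-field models predict — including how
those predictions deform when the probing grating is not matched to the
receptive field.

## The models

A purely spatial **simple cell** is modelled as a scale-normalized
directional derivative of an anisotropic (affine) Gaussian,

    T(x; σ₁, σ₂, φ, m) = σ₁^m ∂_φ^m g(x; Σ_φ),     m ∈ {1, 2},

where Σ_φ has eigenvalues σ₁² (along the preferred orientation φ) and σ₂²
(perpendicular), and κ = σ₂/σ₁ is the scale parameter ratio. Spatio-temporal
variants are either space-time separable (spatial kernel × temporal Gaussian
derivative) or velocity-adapted (spatial profile translating with scalar
velocity v along φ). A **complex cell** is the quasi-quadrature energy
combination √(L₁² + C_φ L₂²) of the first- and second-order responses, with
C_φ = 1/√2. The affine **Gabor** alternative is a Gaussian envelope times a
cos/sin carrier pair with frequency ν.

Probing each model with a sine grating of inclination θ (relative to φ) at
the per-orientation optimal frequency ω̂(θ) — and, for velocity-adapted
fields, the optimal velocity û = v cos θ — gives peak-normalized tuning
curves that depend only on κ:

| model | r(θ) |
|---|---|
| first-order simple | \|cos θ\| / √(cos²θ + κ² sin²θ) |
| second-order simple | cos²θ / (cos²θ + κ² sin²θ) |
| complex (spatial, velocity-adapted) | \|cos θ\|^{3/2} / (cos²θ + κ² sin²θ)^{3/4} |
| complex (separable) | \|cos θ\| √(2 + κ² + (2 − κ²) cos 2θ) / (2 (cos²θ + κ² sin²θ)) |

From any curve the package computes the resultant
R = ∫ r(θ) cos 2θ dθ / ∫ r(θ) dθ on [−π/2, π/2], the circular variance
V = 1 − |R|, and the orientation bandwidth B with r(B) = 1/√2, each with
closed forms for the simple-cell models (e.g. R = κ/(κ+1) for the
second-order model, B = arccos(κ/√(κ²+1)) for the first-order model).

Mismatched probing is covered too: frequency scaling by λ (which cancels),
a fixed, orientation-independent frequency (which narrows the curves and
has its own closed-form resultant in terms of erf), and velocity mismatch
u = μ v cos θ, which replaces κ by the effective
κ̃ = κ / √(1 + (μ−1)² ṽ²) with ṽ = σ_t v / σ₁.

Every closed form is validated by a brute-force oracle: gratings rendered
on rasters, convolved with discretized kernels, amplitudes measured by a
phase sweep, optima recovered by numeric search.

## Worked example

```python
>>> import math
>>> from orisel import canonical_curve, closed_form_resultant, closed_form_bandwidth
>>> canonical_curve("simple2", "spatial", 2.0, math.pi / 4)
0.20000000000000007
>>> closed_form_resultant("simple2", 2.0)
0.6666666666666666
>>> math.degrees(closed_form_bandwidth("simple1", 2.0))
26.565051177077994
```

A second-order simple cell with κ = 2 probed 45° off its preferred
orientation responds at 20% of its peak; its tuning has resultant 2/3
(circular variance 1/3) and the first-order model at the same κ has a
26.6° bandwidth. The same numbers come out of the command line:

```sh
orisel curves --model simple1,simple2,complex --kappa 1,2,4,8 --out curves.csv
orisel measures --out measures.csv
orisel gabor --kappa 1,2,4,8 --sigma1nu 0.5,1,2 --out gabor.csv
orisel validate        # oracle-vs-closed-form suite, nonzero exit on failure
```

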