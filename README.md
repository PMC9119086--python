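# morphoreg

Morphology-model-driven registration of serial-section electron-microscopy
(ssEM) image stacks.

Reconstructing neural tissue in 3-D requires aligning consecutive ultra-thin
sections whose content genuinely differs: structures advance, twist and end
between slices, and the cutting/imaging process adds rotations, shifts and
nonlinear distortion. Not every structure is equally useful for alignment.
Tubular neurites crossing the section plane produce near-circular
cross-sections that change slowly from slice to slice, while irregular
profiles change quickly and mislead matching. `morphoreg` turns that
biological prior into a registration pipeline, together with the stochastic
shape model that justifies it quantitatively.

## The model and the theory

A local sphere-like structure `K` is described by a spherical deformation
model: its normalized radius is

    r(θ, φ) = 1 + Σ_{n≥2} Σ_m a_nm φ_nm(θ, φ),      a_nm ~ N(0, λ_n),
    1/λ_n = α + β (n^p − 2^p),   p > 2, α, β > 0,

with real orthonormal spherical harmonics `φ_nm`. Cutting `K` with two
parallel planes a thickness `d` apart gives a pair of adjacent-section
contours; translating one by a known shift emulates section deformation.
Registering the pair with the closed-form landmark estimator
`Δt̂ = mean(x_iT − x_iS)` has error second moment

    E[(Δt̂ − Δt)²] = r̄² sin²φ / N² · Σ_ij 2 cosθ_i cosθ_j (Cov_iTjT − Cov_iSjT),

driven entirely by the shape variances `λ_n`. Because the Fourier
coefficients `b_n` of a contour's radius function satisfy
`b_n ~ κ_n χ²(2)` with `κ_n ∝ λ_n`, the roundness index

    R = −log Σ_n b_n

ranks regions by their expected registration accuracy: large `R` means
near-circular, stable, and reliable to match.

## The pipeline

1. **Region selection** — membrane probability map (external network output
   or a built-in classical ridge detector) → watershed labeling → per-region
   roundness `R` → keep regions with `R ≥ R_thres` (default 6).
2. **Dense correspondence** — per-pixel gradient-histogram descriptors
   matched by a truncated-L1 discrete flow energy (coarse-to-fine scanline
   Viterbi sweeps); correspondences sampled at grid vertices inside the
   selected mask.
3. **Global adjustment** — displacements of all control points in all
   sections solved simultaneously under the equality constraints that
   matched points coincide (sparse SPD system; no reference section, no
   error accumulation along the stack).
4. **Warping** — each section deformed by rigid moving-least-squares from
   its control-point displacements, preserving local shape and scale.

A synthetic-phantom generator (tubes built from the same sphere model, with
analytic ground-truth flow and the rotation/shift/MLS/TPS deformation
protocols) supports end-to-end evaluation with SSIM and residual metrics.

## Worked example

```python
from morphoreg import (ShapeParams, SectionPairSpec, make_section_pair,
                       LandmarkSet, estimate_translation, empirical_error_moment,
                       theoretical_translation_variance, contour_roundness)

spec = SectionPairSpec()  # thickness 40 px, true shift (4.5, 4.5) px
for label, (alpha, beta) in [("round", (20000.0, 1.0)), ("irregular", (300.0, 0.05))]:
    params = ShapeParams(alpha=alpha, beta=beta)   # p = 4, mean radius 150 px
    S, T = make_section_pair(params, spec, seed=5)
    est = estimate_translation(LandmarkSet.from_contour(S), LandmarkSet.from_contour(T))
    theory = theoretical_translation_variance(params, spec)
    mc = empirical_error_moment(params, spec, reps=2000, seed=2)
    print(f"{label:9s}  R = {contour_roundness(S).R:5.2f}   "
          f"one-pair estimate = ({est.dt:.2f}, {est.ds:.2f}) px   "
          f"X-error variance: theory {theory:.3f}, simulated {mc.second_moment_x:.3f} px^2")
```

prints

```
round      R =  6.07   one-pair estimate = (4.69, 4.23) px   X-error variance: theory 0.769, simulated 0.783 px^2
irregular  R =  2.49   one-pair estimate = (5.36, 3.08) px   X-error variance: theory 32.992, simulated 33.588 px^2
```

The round structure (R above the default threshold 6) recovers the true
(4.5, 4.5) px shift to a fraction of a pixel and its closed-form error
variance matches simulation; the irregular one (R ≈ 2.5) is forty times
less accurate — which is why the pipeline only matches inside round regions.

The `morphoreg` command exposes the same functionality from the shell
(`morphoreg simulate-pair`, `roundness`, `flow`, `optimize`, `register`,
`phantom`, `evaluate`, ...); see `morphoreg --help`.

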