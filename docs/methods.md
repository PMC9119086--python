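# Methods

This note documents the models, numerical choices and limitations behind
`morphoreg`. It is written for users who want to understand what the
package computes and what its synthetic validation does and does not show.

## Spherical deformation model (`sphere_model`)

A local structure is a star-shaped random surface: normalized radius
`r(θ, φ) = 1 + Σ_{n=2}^{n_max} Σ_m a_nm φ_nm(θ, φ)` with independent
`a_nm ~ N(0, λ_n)` and `1/λ_n = α + β(n^p − 2^p)`. Conventions:

- **Harmonics.** Real, fully orthonormal on the sphere: the cosine branch
  (m < 0), zonal (m = 0) and sine branch (m > 0) share
  `(k_n^m)² = (2n+1)(n−|m|)!/(2π (n+|m|)!)` (with `4π` for m = 0), so the
  addition theorem gives `Σ_m φ_nm² = (2n+1)/(4π)` and the pointwise radius
  variance is `Σ_n λ_n (2n+1)/(4π)`. Associated Legendre values come from
  `scipy.special.lpmv`; normalizers are evaluated in log space.
- **Parameters.** `p` (dimensionless, default 4) sets smoothness; `α`
  (global precision) and `β` (local precision) set how much and at which
  scales the surface deviates from a sphere; `mean_radius` r̄ (pixels,
  default 150) and `thickness` d (pixels, default 40) describe a regular
  neurite cross-section and ssEM slice spacing at ~1 nm/px.
- **Truncation.** `n_max = 40`: with p = 4 the tail above degree 40
  contributes < 1e−5 of the total variance for every parameter set in the
  default grid.
- **Section placement.** The two cutting planes are symmetric about the
  equator, `cos φ_{S,T} = ±d/(2r̄)`, which makes `sin φ_S = sin φ_T` hold
  exactly — the assumption the accuracy analysis needs. The "projection" of
  the cap is implemented as the radius profile at the cutting latitude,
  `ρ_i = r̄ sin φ · r(θ_i, φ)` at equally spaced longitudes.
- **Coordinates.** x = column (rightward), y = row (downward), 0-based,
  pixel centers at integers; polar angles counterclockwise from +x.
- **Determinism.** Every sampling routine is a pure function of
  (parameters, seed) via `numpy.random.default_rng`. Contours floor radii
  at 1e−6 px; with the default parameter grid the floor is never active
  (radius standard deviation stays ≲ 0.2 of the mean).
- **Dataset grid.** The default synthetic-dataset design has 11 × 11
  log-spaced subsets, α ∈ [10², 10⁴], β ∈ [10⁻², 10⁰], 1000 pairs each.
  The grid bounds are this package's choice: they span visually
  near-circular to strongly deformed contours while keeping the radius
  field positive (a radius is a distance), which anchors the grid to the
  model's physical domain of validity.
- **Rendering** is binary polygon fill with fixed gray levels (interior
  0.45, 2-px inner boundary 0.15, background 0.85) — no anti-aliasing, so
  renders are bit-reproducible.

## Accuracy theory (`accuracy_theory`)

- The radial covariance is the Legendre series
  `Σ_n λ_n (2n+1)/(4π) P_n(cos ψ)`, evaluated with a Legendre-coefficient
  vector (numerically stable for |cos ψ| ≤ 1, which is enforced by
  clipping).
- The translation-error second moment multiplies that covariance difference
  across same- and cross-section landmark direction pairs; the factor 2
  reflects the equal-latitude symmetry (`Cov_iTjT = Cov_iSjS`). The closed
  form is validated against Monte-Carlo simulation (2000 replicates, 3 SE)
  at several (α, β) settings.
- Fourier coefficients of a contour use the periodic trapezoid rule on the
  equally spaced samples (exact for band-limited inputs; an aliasing guard
  requires ≥ 2·N_harm + 1 samples). With this package's orthonormal
  harmonics the coefficient variance is
  `κ_n = sin²φ₀ Σ_{l≥n} (k_l^n P_l^n(cos φ₀))² λ_l` (`kappa_exact`);
  the widely used leading-term simplification `κ_n ≈ C_n λ_n`
  (`kappa_approx`) is also provided. The leading term always
  *under*-estimates; its relative error is small for even n under fast
  λ-decay but has an irreducible tail (≈ 7% floor at n = 3, p = 4) because
  the ratio of consecutive same-parity λ's is bounded below. Statistical
  tests therefore use the exact series, which is what the `b_n ~ κ_n χ²(2)`
  law is verified against.
- **Roundness index.** `R = −log Σ_{n=1}^{20} b_n`, natural log, computed
  on radii normalized by their mean so R is size-invariant. Degree n = 1 is
  included: it captures residual origin offset and is near zero when the
  centroid is used as origin. A perfect circle would give R = ∞; the sum is
  floored at 1e−12 (R capped ≈ 27.6) to keep scores finite and orderable.
  For real image regions the cutting latitude is unknown and `sin φ₀ = 1`
  (equatorial convention) is used throughout. The default selection
  threshold is `R_thres = 6`.

## Landmark registration (`landmark_registration`)

Landmarks are contour points paired by shared polar angle (no
nearest-neighbor matching); the quadratic cost over a common translation is
minimized in closed form by the per-axis mean coordinate difference. In
simulation the true generator origins are used, matching the theory; for
real regions the centroid stands in. The Monte-Carlo harness
(`empirical_error_moment`) draws coefficient matrices against precomputed
harmonic bases at the two section latitudes — identical in law to
simulating pairs one by one (a consistency test checks the two routes), and
fast enough for thousands of replicates per second.

## Region selection (`region_selection`)

Algorithm: membrane probability map → watershed → per-region R → threshold.

- **Membranes.** Deep segmentation is deliberately an *interface*: an
  external per-pixel probability map (any network's output) is a
  first-class input, validated for geometry and range. The built-in
  classical fallback is a dark-ridge response (inverted intensity,
  difference-of-Gaussians band-pass, clipped and rescaled); it is a
  baseline, not a claim about segmentation quality.
- **Watershed.** Regional minima after h-minima suppression (depth 0.1 on
  [0, 1] maps) seed a 4-connected watershed with watershed lines as label
  0; labels are relabeled contiguously. A constant map yields one region.
- **Region contour.** Boundary pixels (inner 4-connected boundary) are
  binned by angle about the centroid; each bin's radius is the *maximum*
  member distance — lobes of non-star-convex shapes inflate high-order
  Fourier power, which is exactly what the index should penalize. The bin
  count adapts to the boundary length (~2 boundary pixels per bin, clamped
  to [48, 180]) so small regions keep populated bins; isolated empty bins
  are filled by circular interpolation, and a region with > 25% empty bins
  is rejected as degenerate.
- **Filters.** `min_area = 64 px²` (the Fourier quadrature needs boundary
  samples; smaller regions are noise) and border-touching regions are
  excluded (their contour is an artifact of the field of view). Both
  defaults are package choices recorded in the per-region report.

## Dense correspondence (`dense_correspondence`)

Per-pixel descriptors: 4×4 spatial cells × 8 hard-assigned orientation bins
over a 16×16 support, gradient-magnitude weighted, L2-normalized, clipped
at 0.2, renormalized — computed densely with integral images, so they are
exactly equivariant to integer translations away from borders.

The flow energy is truncated-L1 data + L1 magnitude + truncated-L1
first-order smoothness on the 4-neighborhood, over integer displacements in
a square search window. Defaults (`t = 20.48`, `η = 0.01`,
`smooth_weight = 2`, `smooth_trunc = 40`, `search_radius = 16`,
`levels = 3`) were tuned on phantoms and are configuration, not claims.
Out-of-image targets pay the data truncation.

Optimizer: coarse-to-fine **scanline conditional modes**. At each pyramid
level (descriptor fields are 2×2 block-mean downsampled), alternating
red-black row and column sweeps re-optimize every other line *exactly* by
Viterbi dynamic programming given the rest of the field, so the energy is
monotonically non-increasing and the procedure is deterministic. At the
coarsest level a per-label data-cost volume is precomputed and the search
is multi-started from the five best constant displacements — necessary
because the basin of the global optimum (e.g. interior at the true shift,
borders at zero to avoid out-of-image truncation) is often not the
lowest-energy constant's. Finer levels refine the upsampled flow with ±1
moves after probing small uniform corrections (which repairs the parity
bias of 2× upsampling). If the result were ever worse than zero flow, a
zero-initialized descent replaces it, so the returned energy is never above
the zero-flow energy. On twenty 8×8 radius-1 instances the returned energy
equals an exact integer-programming optimum (and is never below it).

Flow is computed on full frames; the region mask gates only correspondence
*emission* at grid vertices (stride `grid_spacing`, offset half a stride),
keeping image context available to the data term.

## Stack optimization (`stack_optimization`)

The energy `Σ |w|² + Σ λ/dist(p,q) · |w_p − w_q|²` is minimized subject to
`p_i + w_i = p_{i+1} + w_{i+1}` for every correspondence. Matched points
are merged into chains by union-find (chains through several sections
collapse transitively; all members share one unknown target position), and
the unconstrained problem in the chain targets is a sparse symmetric
positive-definite system solved per coordinate (dense solve below 200
unknowns, preconditioned conjugate gradients above, tolerance 1e−10, sparse
LU fallback). Constraints hold exactly by construction; the solution
matches a dense KKT oracle to machine precision on test instances.

The neighbor rule `∀(p_i, q_i)` is mutual k-nearest neighbors (k = 4)
within a radius (default 48 px = 3 × grid spacing), with weight `λ/dist`
(closer points couple more strongly — the standard smoothness behavior; a
configuration flag flips to `λ·dist`). λ defaults to 1. Because the energy
and constraints are symmetric in pair direction, reversing the stack
reproduces identical displacements — the formal sense in which no error
accumulates toward either end.

## Warping (`warp`)

- **Rigid MLS.** At each evaluation point the weighted (w = 1/d^{2α_w},
  α_w = 1) 2-D Procrustes rotation about the weighted centroids is solved
  in closed form; this reproduces any global rigid motion of the control
  points exactly. Image warps are backward-mapped: the deformation from
  output pixel to source is the rigid MLS of the swapped control points,
  evaluated on an 8-px lattice and bilinearly interpolated (exact for
  affine maps, so the rigid-reproduction property survives gridding), then
  sampled with bilinear interpolation (coordinates within 1e−6 px of the
  image edge are snapped inside; genuinely outside pixels become 0).
- **Random MLS distortion.** Four control points, one per quadrant, ≥ 50 px
  from each quadrant's edges, displaced uniformly in [−20, 20]² px
  (amplitude configurable).
- **TPS.** `scipy.interpolate.RBFInterpolator` with the thin-plate kernel
  and zero smoothing (exact interpolation); collinear control points are
  rejected. The random TPS protocol draws N(0, σ²) vectors (σ default
  10 px) at uniform positions, with fixed corner anchors bounding the far
  field.
- **Map inversion** (for ground-truth flow through distorted sections) is a
  damped per-point Newton iteration with finite-difference 2×2 Jacobians.

A note on fidelity: double bilinear resampling alone caps achievable SSIM
near 0.96 on images with 2-px membranes (and lower with per-pixel noise),
so round-trip image-recovery tests assert recovery up to that interpolation
limit, not an arbitrary closeness to 1.

## Phantoms (`phantom`)

Tubes are sequences of sphere-model cross-sections: one sampled harmonic
shape per tube, cut at slowly drifting latitudes so adjacent sections are
similar; centers follow smoothed random walks (irregular tubes drift 3×
more — they are the unstable structures). Interiors carry a per-tube
texture field sampled in tube-local coordinates, so texture translates with
the tube and the flow data term has signal; membranes are 2-px dark inner
boundaries; background has mild Gaussian and low-frequency noise. Round
tubes use (α, β) = (4·10⁴, 5) and irregular ones (120, 0.02) — calibrated
so that measured boundary R separates cleanly around the threshold 6
(rasterization itself contributes spectral power ≈ e⁻⁸ at these radii,
which bounds how round a small rasterized region can score).

Deformation protocols: per-section rotation U(−90°, 90°) and shift
U(−100, 100)² px with a random MLS distortion on every 5th section (0-based
indices ≡ 0 mod 5), or per-section random TPS. Ground-truth flow between
deformed sections is composed analytically from the recorded transforms
(affine parts in closed form, MLS/TPS parts through the Newton inverse),
never re-estimated.

What the phantoms do **not** emulate: realistic EM texture statistics,
staining variation, charging or knife artifacts, structure
appearance/disappearance, or anisotropic resolution. Passing end-to-end
tests therefore demonstrates the pipeline's mechanics (selection, matching,
global adjustment, warping) under controlled geometry, not segmentation or
matching performance on real micrographs.

## Pipeline (`pipeline`, `cli`)

Sections are registered into a common frame determined by the global
solution itself (the magnitude term fixes the gauge); there is no reference
section. A section with no selected regions falls back to a full-image
correspondence grid with a warning. Gross offsets beyond the flow search
radius are out of scope for the matcher; an optional phase-correlation
pre-alignment exists as plumbing and is off by default. With fixed
configuration and seed the whole pipeline is bit-deterministic.

End-to-end evaluation reports per-section SSIM (11×11 Gaussian window,
σ = 1.5, K1 = 0.01, K2 = 0.03) against ground truth and against the
adjacent aligned section, and ground-truth correspondence residuals at the
pipeline's own correspondence points before vs after registration.

### Problem sizes used in the shipped validation

Simulation-based checks use 600–5000 replicates (3-SE statistical
tolerances), flow-oracle instances are 8×8 with radius 1 (the scale at
which an exact integer-programming oracle is tractable), and end-to-end
phantom runs use 3–4 sections of 144–160² pixels with translations inside
the flow search radius. These sizes are the package's validation design;
all thresholds are stated in the tests themselves.

## Known limitations

- The flow optimizer guarantees monotone descent and small-instance
  optimality, not global optimality on large frames.
- Rotation-invariant matching is out of scope (descriptors are
  orientation-sensitive); the ±90° protocol rotations are used to generate
  data, but full-pipeline recovery is validated on translations within the
  search radius.
- The classical membrane detector is a baseline; quantitative segmentation
  quality requires an external network's probability maps.
- Selection scores assume regions are roughly star-shaped about their
  centroid; highly concave regions are penalized by design rather than
  measured accurately.
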