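"""Synthetic EM-like section stacks with ground truth.

Tubular neurons are modeled as sequences of sphere-like local structures:
each tube follows a smooth 3-D trajectory and its per-section cross-section
is a contour of the spherical deformation model, so tube roundness is
controlled by the same (alpha, beta) parameters the accuracy theory uses.
Sections get dark 2-px membranes, textured interiors that translate with
the tube (so descriptor matching has something to lock onto), and Gaussian
background noise.

``apply_serial_deformation`` implements the two synthetic-deformation
protocols used for evaluating stack registration: per-section random
rotation/shift with periodic MLS distortion ("fib-sem"), and random TPS
warps ("cremi").  Ground-truth flow between adjacent deformed sections is
computed analytically from the applied transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter, map_coordinates
from skimage.draw import polygon
from skimage.metrics import structural_similarity

from .sphere_model import ShapeParams, project_contour, sample_shape
from .warp import (
    ControlPointSet,
    invert_point_map,
    mls_random_distort,
    mls_rigid_map,
    random_tps_control_points,
    tps_map,
    tps_warp,
    mls_rigid_warp,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and statistics of a synthetic stack."""

    n_sections: int = 6
    height: int = 256
    width: int = 256
    n_tubes: int = 6
    tube_radius_range: tuple[float, float] = (18.0, 28.0)
    #: (alpha, beta) for round tubes; used for all tubes unless irregular
    round_params: tuple[float, float] = (40000.0, 5.0)
    #: (alpha, beta) for irregular tubes
    irregular_params: tuple[float, float] = (120.0, 0.02)
    #: fraction of tubes drawn from the irregular parameter set
    irregular_fraction: float = 0.34
    #: per-section latitude increment of the cutting plane (radians)
    latitude_step: float = 0.04
    #: stddev of the smooth per-section drift of tube centers (pixels)
    drift_sigma: float = 0.6
    #: irregular tubes drift this much more (they are the unstable structures)
    irregular_drift_multiplier: float = 3.0
    background_noise: float = 0.02
    texture_noise: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("a stack needs at least 2 sections")
        if min(self.height, self.width) < 64:
            raise ValueError("canvas too small for a meaningful phantom")


@dataclass(frozen=True)
class SectionTransform:
    """Deformation applied to one section (identity when all fields trivial)."""

    rotation_deg: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    mls_cps: ControlPointSet | None = None
    tps_cps: ControlPointSet | None = None
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.shift == (0.0, 0.0)
            and self.mls_cps is None
            and self.tps_cps is None
        )

    def _affine(self):
        t = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        c = np.asarray(self.center)
        shift = np.asarray(self.shift)
        return rot, c, shift

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Original coordinates -> deformed-image coordinates."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        rot, c, shift = self._affine()
        out = (pts - c) @ rot.T + c + shift
        if self.mls_cps is not None:
            out = invert_point_map(
                lambda q: mls_rigid_map(q, self.mls_cps.inverse), out
            )
        if self.tps_cps is not None:
            out = invert_point_map(lambda q: tps_map(q, self.tps_cps.inverse), out)
        return out

    def backward(self, points: np.ndarray) -> np.ndarray:
        """Deformed-image coordinates -> original coordinates."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if self.tps_cps is not None:
            pts = tps_map(pts, self.tps_cps.inverse)
        if self.mls_cps is not None:
            pts = mls_rigid_map(pts, self.mls_cps.inverse)
        rot, c, shift = self._affine()
        return (pts - shift - c) @ rot + c


@dataclass
class PhantomStack:
    """Images plus aligned ground truth for a synthetic stack."""

    images: np.ndarray          # (S, H, W) float32 in [0, 1]
    labels: np.ndarray          # (S, H, W) int32, 0 = background
    membranes: np.ndarray       # (S, H, W) float32 boundary maps
    transforms: list[SectionTransform]
    spec: PhantomSpec

    @property
    def n_sections(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def gt_point_flow(self, pair: int, points: np.ndarray) -> np.ndarray:
        """Ground-truth displacement at points of deformed section ``pair``.

        A pixel p in deformed section i corresponds to original position
        B_i(p), which appears in deformed section i+1 at F_{i+1}(B_i(p));
        the flow is that position minus p.  (Before deformation the stack is
        aligned, so the pre-deformation flow is identically zero.)
        """
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        orig = self.transforms[pair].backward(pts)
        return self.transforms[pair + 1].forward(orig) - pts

    def gt_flow_dense(self, pair: int, stride: int = 1) -> np.ndarray:
        """Dense ground-truth flow (H, W, 2) for one adjacent pair."""
        h, w = self.shape
        yy, xx = np.mgrid[0:h:stride, 0:w:stride]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        return self.gt_point_flow(pair, pts).reshape(yy.shape + (2,))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _smooth_noise(rng, shape, sigma):
    field = gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def _tube_layout(spec: PhantomSpec, rng) -> list[dict]:
    """Sample non-overlapping tube centers, radii and shape parameters."""
    tubes = []
    margin = spec.tube_radius_range[1] + 6
    n_irregular = int(round(spec.irregular_fraction * spec.n_tubes))
    for t in range(spec.n_tubes):
        r = rng.uniform(*spec.tube_radius_range)
        placed = False
        for _ in range(300):
            cx = rng.uniform(margin, spec.width - margin)
            cy = rng.uniform(margin, spec.height - margin)
            ok = all(
                np.hypot(cx - o["cx"], cy - o["cy"]) > 1.35 * (r + o["radius"])
                for o in tubes
            )
            if ok:
                placed = True
                break
        if not placed:
            warnings.warn(
                f"could not place tube {t} without overlap: phantom saturated"
            )
            continue
        irregular = t < n_irregular
        alpha, beta = spec.irregular_params if irregular else spec.round_params
        sigma = spec.drift_sigma * (spec.irregular_drift_multiplier if irregular else 1.0)
        drift = gaussian_filter(
            rng.standard_normal((spec.n_sections, 2)), sigma=(1.5, 0)
        ) * sigma
        drift = np.cumsum(drift, axis=0)
        drift -= drift.mean(axis=0)
        tubes.append(
            dict(
                cx=cx, cy=cy, radius=r,
                params=ShapeParams(alpha=alpha, beta=beta, mean_radius=r),
                irregular=t < n_irregular,
                drift=drift,
                gray=rng.uniform(0.35, 0.6),
                texture_seed=int(rng.integers(2**31)),
                shape_seed=int(rng.integers(2**31)),
            )
        )
    return tubes


def generate_phantom_stack(spec: PhantomSpec) -> PhantomStack:
    """Render an aligned (undeformed) phantom stack with ground truth.

    Each tube is one sampled local structure cut at slowly varying latitudes
    so adjacent cross-sections are similar; interiors carry a texture field
    that translates with the tube, membranes are 2-px dark inner boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    tubes = _tube_layout(spec, rng)
    s_count, h, w = spec.n_sections, spec.height, spec.width

    images = np.empty((s_count, h, w), dtype=np.float32)
    labels = np.zeros((s_count, h, w), dtype=np.int32)
    membranes = np.zeros((s_count, h, w), dtype=np.float32)

    shapes = [sample_shape(t["params"], t["shape_seed"]) for t in tubes]
    textures = [
        _smooth_noise(np.random.default_rng(t["texture_seed"]), (160, 160), 2.0)
        for t in tubes
    ]
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

    for s in range(s_count):
        bg_rng = np.random.default_rng(spec.seed + 10_000 + s)
        img = 0.78 + spec.background_noise * bg_rng.standard_normal((h, w))
        img += 0.04 * _smooth_noise(bg_rng, (h, w), 12.0)
        lab = np.zeros((h, w), dtype=np.int32)
        mem = np.zeros((h, w), dtype=np.float32)

        for ti, tube in enumerate(tubes):
            phi = np.pi / 2 + (s - (s_count - 1) / 2) * spec.latitude_step
            contour = project_contour(shapes[ti], phi, 180)
            cx = tube["cx"] + tube["drift"][s, 0]
            cy = tube["cy"] + tube["drift"][s, 1]
            xs = cx + contour.radii * np.cos(contour.angles)
            ys = cy + contour.radii * np.sin(contour.angles)
            rr, cc = polygon(ys, xs, shape=(h, w))
            if len(rr) == 0:
                continue
            mask = np.zeros((h, w), dtype=bool)
            mask[rr, cc] = True
            interior = binary_erosion(mask, structure=cross, iterations=2)

            # texture sampled in tube-local coordinates: moves with the tube
            yy, xx = np.nonzero(interior)
            tex = map_coordinates(
                textures[ti],
                [yy - cy + 80.0, xx - cx + 80.0],
                order=1, mode="wrap",
            )
            img[mask] = 0.12  # membrane ring
            img[yy, xx] = tube["gray"] + spec.texture_noise * tex
            lab[mask] = ti + 1
            mem[mask & ~interior] = 1.0

        images[s] = np.clip(img, 0.0, 1.0)
        labels[s] = lab
        membranes[s] = mem

    transforms = [SectionTransform(center=((w - 1) / 2.0, (h - 1) / 2.0)) for _ in range(s_count)]
    return PhantomStack(
        images=images, labels=labels, membranes=membranes, transforms=transforms, spec=spec
    )


# --------------------------------------------------------------------------
# serial deformation protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationProtocol:
    """Amplitudes of the synthetic serial deformations.

    ``fib-sem``: per-section rotation U(-rotation_deg, rotation_deg) and
    shift U(-shift_px, shift_px)^2, plus a random 4-control-point rigid-MLS
    distortion on every ``mls_every``-th section (0-based indices 0, 5, ...).
    ``cremi``: per-section TPS warp with normal random vectors.
    """

    kind: str = "fib-sem"
    rotation_deg: float = 90.0
    shift_px: float = 100.0
    mls_every: int = 5
    mls_max_displacement: float = 20.0
    mls_margin: float = 50.0
    tps_sigma: float = 10.0
    tps_n_points: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("fib-sem", "cremi"):
            raise ValueError(f"unknown protocol kind: {self.kind!r}")


def _warp_section(image, labels, membranes, transform: SectionTransform):
    """Resample one section (image bilinear, labels nearest) under a transform."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = transform.backward(pts)
    coords = [src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)]
    img = map_coordinates(image.astype(np.float64), coords, order=1, cval=0.0)
    lab = map_coordinates(labels, coords, order=0, cval=0)
    mem = map_coordinates(membranes.astype(np.float64), coords, order=1, cval=0.0)
    return img.astype(np.float32), lab.astype(np.int32), mem.astype(np.float32)


def apply_serial_deformation(
    stack: PhantomStack, protocol: DeformationProtocol, seed: int
) -> PhantomStack:
    """Deform every section of an aligned stack per the chosen protocol.

    Returns a new stack whose ``transforms`` record the applied deformations;
    ground-truth flow between deformed sections follows analytically from
    them (``gt_point_flow`` / ``gt_flow_dense``).
    """
    rng = np.random.default_rng(seed)
    s_count = stack.n_sections
    h, w = stack.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    transforms: list[SectionTransform] = []
    for s in range(s_count):
        if protocol.kind == "fib-sem":
            rot = float(rng.uniform(-protocol.rotation_deg, protocol.rotation_deg))
            shift = tuple(rng.uniform(-protocol.shift_px, protocol.shift_px, 2))
            mls_cps = None
            if protocol.mls_every > 0 and s % protocol.mls_every == 0 and (
                protocol.mls_max_displacement > 0
            ):
                mls_seed = int(rng.integers(2**31))
                _, mls_cps = mls_random_distort(
                    np.zeros((h, w), dtype=np.float32),
                    mls_seed,
                    max_displacement=protocol.mls_max_displacement,
                    margin=protocol.mls_margin,
                )
            transforms.append(
                SectionTransform(rotation_deg=rot, shift=shift, mls_cps=mls_cps, center=center)
            )
        else:  # cremi
            tps_seed = int(rng.integers(2**31))
            if protocol.tps_sigma > 0:
                cps = random_tps_control_points(
                    (h, w), tps_seed, n_points=protocol.tps_n_points, sigma=protocol.tps_sigma
                )
            else:
                cps = None
            transforms.append(SectionTransform(tps_cps=cps, center=center))

    images = np.empty_like(stack.images)
    labels = np.empty_like(stack.labels)
    membranes = np.empty_like(stack.membranes)
    for s, tf in enumerate(transforms):
        if tf.is_identity:
            images[s], labels[s], membranes[s] = (
                stack.images[s], stack.labels[s], stack.membranes[s]
            )
        else:
            images[s], labels[s], membranes[s] = _warp_section(
                stack.images[s], stack.labels[s], stack.membranes[s], tf
            )
    return PhantomStack(
        images=images, labels=labels, membranes=membranes,
        transforms=transforms, spec=stack.spec,
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def ssim_score(image: np.ndarray, reference: np.ndarray, data_range: float | None = None) -> float:
    """Structural similarity with an 11x11 Gaussian window, sigma 1.5.

    ``data_range`` defaults to 1.0 for floating-point images and to the type
    range for integer images.
    """
    image = np.asarray(image)
    reference = np.asarray(reference)
    if image.shape != reference.shape:
        raise ValueError("image geometries do not match")
    if data_range is None:
        data_range = 1.0 if np.issubdtype(image.dtype, np.floating) else float(
            np.iinfo(image.dtype).max
        )
    return float(
        structural_similarity(
            image, reference,
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            K1=0.01, K2=0.03, data_range=data_range,
        )
    )


@dataclass(frozen=True)
class ResidualStats:
    mean: float
    median: float
    variance: float
    n: int


def correspondence_residual(
    gt_disp: np.ndarray,
    est_disp: np.ndarray,
    inside_mask: np.ndarray | None = None,
) -> dict[str, ResidualStats]:
    """Statistics of ||estimated - ground-truth|| displacement.

    ``inside_mask`` (boolean per point) splits the report into overall /
    inside / outside strata.  Points with non-finite ground truth are
    excluded.
    """
    gt = np.asarray(gt_disp, dtype=float).reshape(-1, 2)
    est = np.asarray(est_disp, dtype=float).reshape(-1, 2)
    if gt.shape != est.shape:
        raise ValueError("displacement arrays must have equal shape")
    finite = np.all(np.isfinite(gt), axis=1) & np.all(np.isfinite(est), axis=1)
    if not finite.any():
        raise ValueError("no valid points to evaluate")
    err = np.linalg.norm(est[finite] - gt[finite], axis=1)

    def stats(e):
        return ResidualStats(
            mean=float(e.mean()), median=float(np.median(e)),
            variance=float(e.var()), n=int(e.size),
        )

    out = {"overall": stats(err)}
    if inside_mask is not None:
        m = np.asarray(inside_mask, dtype=bool).reshape(-1)[finite]
        if m.any():
            out["inside"] = stats(err[m])
        if (~m).any():
            out["outside"] = stats(err[~m])
    return out
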