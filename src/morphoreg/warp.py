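"""Control-point image deformation: rigid moving-least-squares and TPS.

Rigid MLS preserves local shape and scale: at every evaluation point the
control points are fit by the best weighted rigid transform (weights
1/|p - src_i|^(2 alpha_w)), which reproduces any global rigid motion of the
control points exactly.  Thin-plate-spline warping (r^2 log r kernel +
affine part) interpolates the control displacements exactly and drives the
synthetic nonlinear-deformation protocols.

All image warps use backward mapping: the deformation is evaluated from the
output pixel back into the source image, followed by bilinear sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator
from scipy.ndimage import map_coordinates

DEFAULT_MLS_ALPHA = 1.0
DEFAULT_GRID_STEP = 8
_EPS = 1e-9


@dataclass(frozen=True)
class ControlPointSet:
    """Paired control points: src moves to dst."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        if src.shape != dst.shape:
            raise ValueError("src and dst must have equal shape")
        if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
            raise ValueError("control points must be finite")
        if len(src) and len(np.unique(src, axis=0)) != len(src):
            raise ValueError("duplicate src control points")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)

    def __len__(self) -> int:
        return len(self.src)

    @property
    def inverse(self) -> "ControlPointSet":
        return ControlPointSet(src=self.dst, dst=self.src)


# --------------------------------------------------------------------------
# rigid MLS
# --------------------------------------------------------------------------

def mls_rigid_map(
    points: np.ndarray, cps: ControlPointSet, alpha_w: float = DEFAULT_MLS_ALPHA
) -> np.ndarray:
    """Rigid-MLS image of query ``points`` (M, 2) under src -> dst.

    At each query v the weighted 2-D Procrustes rotation is closed-form:
    with centroids p*, q* and centered points p̂, q̂,
    cos/sin of the rotation are proportional to sum w q̂·p̂ and
    sum w q̂·p̂⊥; then f(v) = R (v - p*) + q*.  A query coinciding with a
    src control point maps exactly to its dst.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(cps) == 0:
        return pts.copy()
    src, dst = cps.src, cps.dst
    if len(cps) == 1:
        return pts + (dst[0] - src[0])

    d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1)  # (M, K)
    w = 1.0 / np.maximum(d2, _EPS**2) ** alpha_w
    wsum = w.sum(axis=1, keepdims=True)
    p_star = (w @ src) / wsum
    q_star = (w @ dst) / wsum
    p_hat = src[None, :, :] - p_star[:, None, :]   # (M, K, 2)
    q_hat = dst[None, :, :] - q_star[:, None, :]

    a = np.einsum("mk,mki,mki->m", w, q_hat, p_hat)
    p_perp = np.stack([-p_hat[..., 1], p_hat[..., 0]], axis=-1)
    b = np.einsum("mk,mki,mki->m", w, q_hat, p_perp)
    norm = np.hypot(a, b)
    norm = np.where(norm < _EPS, 1.0, norm)
    cos_t, sin_t = a / norm, b / norm

    d = pts - p_star
    out = np.empty_like(pts)
    out[:, 0] = cos_t * d[:, 0] - sin_t * d[:, 1] + q_star[:, 0]
    out[:, 1] = sin_t * d[:, 0] + cos_t * d[:, 1] + q_star[:, 1]

    # snap queries coincident with control points to their exact targets
    hit_q, hit_k = np.nonzero(d2 < _EPS**2)
    out[hit_q] = dst[hit_k]
    return out


def _dense_backward_map(
    shape: tuple[int, int],
    map_fn,
    grid_step: int,
) -> np.ndarray:
    """Evaluate a point map on a coarse grid and bilinearly upsample.

    Returns an (H, W, 2) array of (x, y) source coordinates per output pixel.
    """
    h, w = shape
    gy = np.unique(np.r_[np.arange(0, h, grid_step), h - 1])
    gx = np.unique(np.r_[np.arange(0, w, grid_step), w - 1])
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    mapped = map_fn(np.column_stack([xx.ravel(), yy.ravel()]).astype(float))
    mapped = mapped.reshape(len(gy), len(gx), 2)
    interp = RegularGridInterpolator((gy, gx), mapped, method="linear")
    yy_full, xx_full = np.mgrid[0:h, 0:w]
    return interp(np.stack([yy_full.ravel(), xx_full.ravel()], axis=-1)).reshape(h, w, 2)


def _resample(image: np.ndarray, coords_xy: np.ndarray) -> np.ndarray:
    """Bilinear backward sampling; out-of-source pixels filled with 0.

    Coordinates within 1e-6 px of the valid range are snapped onto it:
    map_coordinates treats even infinitesimally negative coordinates as
    fully outside.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    x = coords_xy[..., 0]
    y = coords_xy[..., 1]
    xc = np.clip(x, 0.0, w - 1.0)
    yc = np.clip(y, 0.0, h - 1.0)
    x = np.where(np.abs(x - xc) <= 1e-6, xc, x)
    y = np.where(np.abs(y - yc) <= 1e-6, yc, y)
    return map_coordinates(img, [y, x], order=1, mode="constant", cval=0.0).astype(
        np.float32
    )


def mls_rigid_warp(
    image: np.ndarray,
    cps: ControlPointSet,
    grid_step: int = DEFAULT_GRID_STEP,
    alpha_w: float = DEFAULT_MLS_ALPHA,
) -> np.ndarray:
    """Warp an image so its content at src moves to dst (rigid MLS).

    The backward map (output pixel -> source coordinate) is the rigid MLS
    transform of the swapped control points (dst -> src), evaluated on a
    ``grid_step`` lattice and bilinearly interpolated between nodes.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if len(cps) == 0:
        return image.astype(np.float32).copy()
    back = cps.inverse
    coords = _dense_backward_map(image.shape, lambda q: mls_rigid_map(q, back, alpha_w), grid_step)
    return _resample(image, coords)


def mls_random_distort(
    image: np.ndarray,
    seed: int,
    max_displacement: float = 20.0,
    margin: float = 50.0,
) -> tuple[np.ndarray, ControlPointSet]:
    """Random rigid-MLS distortion with four control points.

    The image is split by the central cross into four parts; one control
    point is drawn uniformly in each part at least ``margin`` pixels from
    that part's edges, then displaced by a uniform random vector in
    [-max_displacement, max_displacement]^2.  Returns the distorted image
    and the ground-truth control points.
    """
    image = np.asarray(image)
    h, w = image.shape
    hh, hw = h / 2.0, w / 2.0
    if hh <= 2 * margin or hw <= 2 * margin:
        raise ValueError(
            f"image {h}x{w} too small for margin {margin} within each quadrant"
        )
    rng = np.random.default_rng(seed)
    src = []
    for qy in (0.0, hh):
        for qx in (0.0, hw):
            x = rng.uniform(qx + margin, qx + hw - margin)
            y = rng.uniform(qy + margin, qy + hh - margin)
            src.append((x, y))
    src = np.array(src)
    disp = rng.uniform(-max_displacement, max_displacement, size=(4, 2))
    cps = ControlPointSet(src=src, dst=src + disp)
    return mls_rigid_warp(image, cps), cps


# --------------------------------------------------------------------------
# thin-plate splines
# --------------------------------------------------------------------------

def tps_map(points: np.ndarray, cps: ControlPointSet) -> np.ndarray:
    """TPS image of query points under src -> dst (exact at control points)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(cps) < 3:
        raise ValueError("TPS needs at least 3 control points")
    span = cps.src - cps.src.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-8) < 2:
        raise ValueError("control points are collinear: TPS is degenerate")
    interp = RBFInterpolator(cps.src, cps.dst, kernel="thin_plate_spline", smoothing=0.0)
    return interp(pts)


def tps_warp(image: np.ndarray, cps: ControlPointSet, grid_step: int = 1) -> np.ndarray:
    """Warp an image with a thin-plate spline moving src to dst.

    Backward-mapped: the TPS is fit from dst to src and sampled bilinearly.
    ``grid_step > 1`` evaluates the map on a lattice and interpolates, like
    the MLS warp.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    back = cps.inverse
    if grid_step > 1:
        coords = _dense_backward_map(image.shape, lambda q: tps_map(q, back), grid_step)
    else:
        h, w = image.shape
        yy, xx = np.mgrid[0:h, 0:w]
        coords = tps_map(
            np.column_stack([xx.ravel(), yy.ravel()]).astype(float), back
        ).reshape(h, w, 2)
    return _resample(image, coords)


def random_tps_control_points(
    shape: tuple[int, int],
    seed: int,
    n_points: int = 8,
    sigma: float = 10.0,
    margin: float = 20.0,
) -> ControlPointSet:
    """Random TPS deformation protocol: normal displacement vectors at
    uniform random positions (plus fixed corner anchors keeping the far
    field bounded)."""
    h, w = shape
    rng = np.random.default_rng(seed)
    pos = np.column_stack(
        [
            rng.uniform(margin, w - margin, n_points),
            rng.uniform(margin, h - margin, n_points),
        ]
    )
    vec = rng.normal(0.0, sigma, size=(n_points, 2))
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]]
    )
    src = np.vstack([pos, corners])
    dst = np.vstack([pos + vec, corners])
    return ControlPointSet(src=src, dst=dst)


def invert_point_map(map_fn, targets: np.ndarray, max_iter: int = 60, tol: float = 1e-8):
    """Solve map_fn(x) = target by Newton iteration with numerical Jacobians.

    Intended for smooth near-identity maps (MLS / TPS distortions); each
    point gets its own finite-difference 2x2 Jacobian, with a plain residual
    step as fallback where the Jacobian is near-singular.
    """
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    x = targets.copy()
    h = 1e-4
    for _ in range(max_iter):
        f0 = map_fn(x)
        res = targets - f0
        if np.abs(res).max() < tol:
            break
        fx = map_fn(x + np.array([h, 0.0]))
        fy = map_fn(x + np.array([0.0, h]))
        a = (fx[:, 0] - f0[:, 0]) / h  # dFx/dx
        c = (fx[:, 1] - f0[:, 1]) / h  # dFy/dx
        b = (fy[:, 0] - f0[:, 0]) / h  # dFx/dy
        d = (fy[:, 1] - f0[:, 1]) / h  # dFy/dy
        det = a * d - b * c
        ok = np.abs(det) > 1e-9
        det_safe = np.where(ok, det, 1.0)
        step = np.empty_like(res)
        step[:, 0] = (d * res[:, 0] - b * res[:, 1]) / det_safe
        step[:, 1] = (-c * res[:, 0] + a * res[:, 1]) / det_safe
        step[~ok] = res[~ok]
        # damp oversized steps to keep the iteration stable
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        scale = np.where(norm > 25.0, 25.0 / np.maximum(norm, 1e-12), 1.0)
        step = step * scale
        x = x + step
    return x
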