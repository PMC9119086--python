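"""Dense descriptor-flow matching between adjacent sections.

Per-pixel gradient-orientation-histogram descriptors (SIFT-like: 4x4 spatial
cells x 8 orientation bins over a 16x16 support) are matched by minimizing a
discrete flow energy with a truncated-L1 data term, an L1 displacement
magnitude term and a truncated-L1 first-order smoothness term over the
4-neighborhood:

    E(w) = sum_p min(||s1(p) - s2(p + w(p))||_1, t)
         + sum_p eta (|u(p)| + |v(p)|)
         + sum_{(p,q)} min(a |u(p)-u(q)|, d) + min(a |v(p)-v(q)|, d)

The optimizer is a coarse-to-fine checkerboard iterated-conditional-modes
sweep over integer displacements: exact coordinate descent per pixel, so the
energy never increases within a level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

DESCRIPTOR_DIM = 128


@dataclass(frozen=True)
class FlowParams:
    """Energy weights and search geometry for descriptor flow.

    The data truncation ``t`` and the pairwise weight/truncation are on the
    scale of L1 descriptor distances (descriptors are L2-normalized, clipped
    at 0.2 and renormalized, so distances live roughly in [0, 12]).
    """

    t: float = 4 * DESCRIPTOR_DIM * 0.04
    eta: float = 0.01
    smooth_weight: float = 2.0
    smooth_trunc: float = 40.0
    search_radius: int = 16
    levels: int = 3
    max_sweeps: int = 10

    def __post_init__(self) -> None:
        if min(self.t, self.eta, self.smooth_weight, self.smooth_trunc) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass
class FlowField:
    """Per-pixel integer displacement (u, v): p in image 1 matches p + w in image 2."""

    u: np.ndarray
    v: np.ndarray
    search_radius: int
    energy: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


# --------------------------------------------------------------------------
# descriptors
# --------------------------------------------------------------------------

def dense_descriptors(image: np.ndarray, n_orientations: int = 8, cell: int = 4) -> np.ndarray:
    """Per-pixel SIFT-like descriptor field (H, W, 128), float32.

    4x4 spatial cells of ``cell`` x ``cell`` pixels over a 16x16 support
    centered at each pixel, 8 hard-assigned orientation bins weighted by
    gradient magnitude; L2-normalized, clipped at 0.2, renormalized.
    Deterministic, and equivariant to integer translations away from the
    borders.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    support = 4 * cell
    if min(img.shape) < support:
        raise ValueError(f"image smaller than the {support}x{support} descriptor support")
    h, w = img.shape

    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    bins = (ori / (2 * np.pi / n_orientations)).astype(int) % n_orientations

    half = support // 2
    desc = np.empty((h, w, 16 * n_orientations), dtype=np.float32)
    for k in range(n_orientations):
        layer = np.where(bins == k, mag, 0.0)
        padded = np.pad(layer, half, mode="constant")
        # integral image -> sums over cell x cell blocks at every offset
        ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
        ii[1:, 1:] = padded.cumsum(0).cumsum(1)
        for a in range(4):
            for b in range(4):
                y0 = np.arange(h) + a * cell  # == y - half + a*cell in padded coords
                x0 = np.arange(w) + b * cell
                block = (
                    ii[np.ix_(y0 + cell, x0 + cell)]
                    - ii[np.ix_(y0, x0 + cell)]
                    - ii[np.ix_(y0 + cell, x0)]
                    + ii[np.ix_(y0, x0)]
                )
                desc[:, :, (a * 4 + b) * n_orientations + k] = block

    norms = np.linalg.norm(desc, axis=2, keepdims=True)
    np.divide(desc, norms, out=desc, where=norms > 0)
    np.clip(desc, None, 0.2, out=desc)
    norms = np.linalg.norm(desc, axis=2, keepdims=True)
    np.divide(desc, norms, out=desc, where=norms > 0)
    return desc


# --------------------------------------------------------------------------
# energy
# --------------------------------------------------------------------------

def _data_cost(d1: np.ndarray, d2: np.ndarray, u: np.ndarray, v: np.ndarray, t: float):
    """Truncated-L1 data cost per pixel; out-of-image targets pay t."""
    h, w, _ = d1.shape
    ys, xs = np.mgrid[0:h, 0:w]
    ty, tx = ys + v, xs + u
    valid = (ty >= 0) & (ty < h) & (tx >= 0) & (tx < w)
    tyc, txc = np.clip(ty, 0, h - 1), np.clip(tx, 0, w - 1)
    l1 = np.abs(d1 - d2[tyc, txc]).sum(axis=2)
    return np.where(valid, np.minimum(l1, t), t)


def _smooth_cost_pairs(u: np.ndarray, v: np.ndarray, params: FlowParams) -> float:
    a, d = params.smooth_weight, params.smooth_trunc
    total = 0.0
    for axis in (0, 1):
        du = np.abs(np.diff(u, axis=axis))
        dv = np.abs(np.diff(v, axis=axis))
        total += np.minimum(a * du, d).sum() + np.minimum(a * dv, d).sum()
    return float(total)


def flow_energy(d1: np.ndarray, d2: np.ndarray, flow: FlowField, params: FlowParams) -> float:
    """Total discrete flow energy of a displacement field."""
    if d1.shape != d2.shape:
        raise ValueError("descriptor field geometries do not match")
    if flow.u.shape != d1.shape[:2]:
        raise ValueError("flow geometry does not match the descriptor fields")
    data = _data_cost(d1, d2, flow.u, flow.v, params.t).sum()
    mag = params.eta * (np.abs(flow.u).sum() + np.abs(flow.v).sum())
    return float(data + mag + _smooth_cost_pairs(flow.u, flow.v, params))


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

def _truncated_l1(delta, params: FlowParams):
    return np.minimum(params.smooth_weight * np.abs(delta), params.smooth_trunc)


def _data_cost_volume(d1, d2, params: FlowParams) -> np.ndarray:
    """Data + magnitude cost for every displacement in the search window.

    Shape (L, H, W) with label index (dv + r) * (2r + 1) + (du + r); built
    once per pyramid level so sweeps become table lookups.
    """
    r = params.search_radius
    h, w, _ = d1.shape
    side = 2 * r + 1
    vol = np.empty((side * side, h, w))
    for dv in range(-r, r + 1):
        for du in range(-r, r + 1):
            idx = (dv + r) * side + (du + r)
            vol[idx] = _data_cost(
                d1, d2, np.full((h, w), du), np.full((h, w), dv), params.t
            ) + params.eta * (abs(du) + abs(dv))
    return vol


def _transpose_volume(vol: np.ndarray, r: int) -> np.ndarray:
    """Cost volume for the transposed geometry (u and v swap roles)."""
    side = 2 * r + 1
    perm = np.arange(side * side).reshape(side, side).T.ravel()
    return np.ascontiguousarray(vol[perm].transpose(0, 2, 1))


def _sweep_lines(
    d1, d2, u, v, params: FlowParams, move_radius: int, parity: int,
    vol: np.ndarray | None = None,
):
    """Exactly re-optimize every other scanline by Viterbi DP.

    Lines of the given parity are conditionally independent given the rest
    of the field, so each is replaced by its exact conditional minimizer
    over the per-pixel candidate moves (current flow +- move_radius, clipped
    to the search window).  ``vol`` supplies precomputed data+magnitude
    costs.  Returns True if anything changed.
    """
    h, w, _ = d1.shape
    rows = np.arange(parity, h, 2)
    n_rows = len(rows)
    if n_rows == 0:
        return False
    moves = np.array(
        [
            (du, dv)
            for dv in range(-move_radius, move_radius + 1)
            for du in range(-move_radius, move_radius + 1)
        ]
    )
    n_moves = len(moves)
    r = params.search_radius

    cu = u[rows][:, :, None] + moves[:, 0][None, None, :]  # (R, W, K)
    cv = v[rows][:, :, None] + moves[:, 1][None, None, :]
    feasible = (np.abs(cu) <= r) & (np.abs(cv) <= r)

    if vol is not None:
        side = 2 * r + 1
        lab = (np.clip(cv, -r, r) + r) * side + (np.clip(cu, -r, r) + r)
        unary = vol[lab, rows[:, None, None], np.arange(w)[None, :, None]]
    else:
        # data term: gather descriptor distances at each candidate target
        ys = rows[:, None, None] + cv
        xs = np.arange(w)[None, :, None] + cu
        valid = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ysc, xsc = np.clip(ys, 0, h - 1), np.clip(xs, 0, w - 1)
        l1 = np.abs(d1[rows][:, :, None, :] - d2[ysc, xsc]).sum(axis=-1)
        unary = np.where(valid, np.minimum(l1, params.t), params.t)
        unary = unary + params.eta * (np.abs(cu) + np.abs(cv))

    # vertical smoothness against the (fixed) adjacent lines
    for off in (-1, 1):
        neighbor = rows + off
        ok = (neighbor >= 0) & (neighbor < h)
        nb = np.clip(neighbor, 0, h - 1)
        contrib = _truncated_l1(cu - u[nb][:, :, None], params) + _truncated_l1(
            cv - v[nb][:, :, None], params
        )
        unary += np.where(ok[:, None, None], contrib, 0.0)
    unary = np.where(feasible, unary, np.inf)

    # Viterbi along x with per-pixel candidate labels
    back = np.empty((w, n_rows, n_moves), dtype=np.int16)
    cost = unary[:, 0, :]
    for x in range(1, w):
        pair = _truncated_l1(cu[:, x - 1, :, None] - cu[:, x, None, :], params)
        pair += _truncated_l1(cv[:, x - 1, :, None] - cv[:, x, None, :], params)
        total = cost[:, :, None] + pair  # (R, K, K)
        back[x] = np.argmin(total, axis=1)
        cost = unary[:, x, :] + np.min(total, axis=1)

    labels = np.empty((n_rows, w), dtype=np.int64)
    labels[:, w - 1] = np.argmin(cost, axis=1)
    for x in range(w - 1, 0, -1):
        labels[:, x - 1] = back[x][np.arange(n_rows), labels[:, x]]

    new_u = np.take_along_axis(cu, labels[:, :, None], axis=2)[:, :, 0]
    new_v = np.take_along_axis(cv, labels[:, :, None], axis=2)[:, :, 0]
    changed = bool(np.any(new_u != u[rows]) or np.any(new_v != v[rows]))
    u[rows] = new_u
    v[rows] = new_v
    return changed


def _icm_level(d1, d2, u, v, params: FlowParams, move_radius: int, vol=None):
    """Iterated conditional modes at scanline granularity for one level.

    Alternating red-black row and column sweeps, each replacing a line by its
    exact conditional minimizer (Viterbi), so the level energy is
    non-increasing; stops when a full round changes nothing.
    """
    d1t = np.ascontiguousarray(d1.transpose(1, 0, 2))
    d2t = np.ascontiguousarray(d2.transpose(1, 0, 2))
    volt = _transpose_volume(vol, params.search_radius) if vol is not None else None
    for _ in range(params.max_sweeps):
        changed = False
        for parity in (0, 1):
            changed |= _sweep_lines(d1, d2, u, v, params, move_radius, parity, vol)
        for parity in (0, 1):
            # transposed geometry: u and v swap roles along the axes
            changed |= _sweep_lines(d1t, d2t, v.T, u.T, params, move_radius, parity, volt)
        if not changed:
            break
    return u, v


def _ranked_constant_flows(vol: np.ndarray, r: int):
    """Constant displacements sorted by summed cost (ascending, ties lexical)."""
    side = 2 * r + 1
    sums = vol.sum(axis=(1, 2))
    ranked = [
        (float(sums[(dv + r) * side + (du + r)]), (du, dv))
        for dv in range(-r, r + 1)
        for du in range(-r, r + 1)
    ]
    ranked.sort(key=lambda t: (t[0], t[1]))
    return ranked


def _downsample_field(d: np.ndarray) -> np.ndarray:
    """2x2 block mean over the spatial dimensions (odd trailing row/col dropped)."""
    h, w, c = d.shape
    h2, w2 = h // 2, w // 2
    return d[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2, c).mean(axis=(1, 3))


def match_flow(d1: np.ndarray, d2: np.ndarray, params: FlowParams | None = None) -> FlowField:
    """Minimize the flow energy by coarse-to-fine checkerboard ICM.

    At the coarsest level the search starts from the best constant
    displacement in the (possibly reduced) search window; finer levels refine
    the upsampled flow with +-1 moves per sweep.  The returned energy is
    never above that of the zero flow, and the whole procedure is
    deterministic.
    """
    if params is None:
        params = FlowParams()
    if d1.shape != d2.shape:
        raise ValueError("descriptor field geometries do not match")
    h, w, _ = d1.shape

    # pyramid of descriptor fields (keep the coarsest level >= 8 px)
    pyramids = [(d1, d2)]
    for _ in range(params.levels - 1):
        a, b = pyramids[-1]
        if min(a.shape[0], a.shape[1]) < 16:
            break
        pyramids.append((_downsample_field(a), _downsample_field(b)))

    u = v = None
    for level in range(len(pyramids) - 1, -1, -1):
        da, db = pyramids[level]
        level_radius = max(1, int(np.ceil(params.search_radius / 2**level)))
        level_params = replace(params, search_radius=level_radius)
        if u is None:
            # coarsest level: multi-start ICM from the best few constant
            # flows (the lowest-energy constant's basin is not always the
            # global one when out-of-image truncation competes with texture)
            hh, ww = da.shape[:2]
            vol = _data_cost_volume(da, db, level_params)
            ranked = _ranked_constant_flows(vol, level_radius)
            best_uv = None
            best_e = np.inf
            for _, (du0, dv0) in ranked[:5]:
                cu = np.full((hh, ww), du0)
                cv = np.full((hh, ww), dv0)
                cu, cv = _icm_level(
                    da, db, cu, cv, level_params, min(2, level_radius), vol=vol
                )
                e = flow_energy(da, db, FlowField(cu, cv, level_radius), level_params)
                if e < best_e:
                    best_e, best_uv = e, (cu, cv)
            u, v = best_uv
            continue
        else:
            u = np.repeat(np.repeat(u * 2, 2, axis=0), 2, axis=1)[: da.shape[0], : da.shape[1]]
            v = np.repeat(np.repeat(v * 2, 2, axis=0), 2, axis=1)[: da.shape[0], : da.shape[1]]
            if u.shape != da.shape[:2]:  # odd sizes: pad with edge values
                pad_y = da.shape[0] - u.shape[0]
                pad_x = da.shape[1] - u.shape[1]
                u = np.pad(u, ((0, pad_y), (0, pad_x)), mode="edge")
                v = np.pad(v, ((0, pad_y), (0, pad_x)), mode="edge")
            u = np.clip(u, -level_radius, level_radius)
            v = np.clip(v, -level_radius, level_radius)
            # upsampling halves resolution parity: probe small uniform
            # corrections of the whole field before refining pixelwise
            best = (0, 0)
            best_e = None
            for dv in range(-2, 3):
                for du in range(-2, 3):
                    nu = np.clip(u + du, -level_radius, level_radius)
                    nv = np.clip(v + dv, -level_radius, level_radius)
                    e = flow_energy(
                        da, db, FlowField(nu, nv, level_radius), level_params
                    )
                    if best_e is None or e < best_e:
                        best_e, best = e, (du, dv)
            u = np.clip(u + best[0], -level_radius, level_radius)
            v = np.clip(v + best[1], -level_radius, level_radius)
            move_radius = 1
        u, v = _icm_level(da, db, u, v, level_params, move_radius)

    flow = FlowField(u=u.astype(np.int64), v=v.astype(np.int64), search_radius=params.search_radius)
    flow.energy = flow_energy(d1, d2, flow, params)

    zero = FlowField(u=np.zeros((h, w), dtype=np.int64), v=np.zeros((h, w), dtype=np.int64),
                     search_radius=params.search_radius)
    zero_energy = flow_energy(d1, d2, zero, params)
    if zero_energy < flow.energy:
        u0, v0 = _icm_level(d1, d2, zero.u.copy(), zero.v.copy(), params, 1)
        zero = FlowField(u=u0, v=v0, search_radius=params.search_radius)
        zero.energy = flow_energy(d1, d2, zero, params)
        if zero.energy < flow.energy:
            flow = zero
    return flow


# --------------------------------------------------------------------------
# correspondence sampling
# --------------------------------------------------------------------------

def grid_correspondences(
    flow: FlowField, mask: np.ndarray | None, spacing: int
) -> tuple[np.ndarray, np.ndarray]:
    """Matched point pairs at masked grid vertices.

    Vertices sit on an interior grid with stride ``spacing`` (offset
    spacing // 2); a vertex p is emitted iff mask(p) is selected, paired with
    p + w(p); pairs whose target falls outside the image are dropped.
    Returns (src, dst) arrays of shape (K, 2) in (x, y) pixel coordinates.
    """
    if spacing < 1:
        raise ValueError("grid spacing must be >= 1")
    h, w = flow.shape
    if mask is not None and mask.shape != (h, w):
        raise ValueError("mask geometry does not match the flow field")
    ys = np.arange(spacing // 2, h, spacing)
    xs = np.arange(spacing // 2, w, spacing)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    gy, gx = gy.ravel(), gx.ravel()
    if mask is not None:
        sel = mask[gy, gx].astype(bool)
        gy, gx = gy[sel], gx[sel]
    tx = gx + flow.u[gy, gx]
    ty = gy + flow.v[gy, gx]
    inside = (tx >= 0) & (tx < w) & (ty >= 0) & (ty < h)
    src = np.column_stack([gx[inside], gy[inside]]).astype(float)
    dst = np.column_stack([tx[inside], ty[inside]]).astype(float)
    return src, dst
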