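"""Morphology-driven region selection for section images.

Pipeline: membrane probability map -> watershed label map -> per-region
boundary contour -> Fourier roundness index R -> threshold selection.
Regions with R >= R_thres are the sphere-like "stable" structures whose
contours the accuracy theory predicts to register most reliably; only
correspondences inside the resulting mask feed the stack optimization.

Membrane segmentation itself is a pluggable interface: a deep network's
probability map can be supplied as an external file, and a classical
dark-ridge detector is provided as the built-in fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .accuracy_theory import DEFAULT_N_HARM, DEFAULT_R_THRES, contour_roundness
from .sphere_model import Contour

DEFAULT_MIN_AREA = 64
DEFAULT_H_MINIMA = 0.1
DEFAULT_N_ANGLES = 180


# --------------------------------------------------------------------------
# membrane probability maps
# --------------------------------------------------------------------------

def segment_membranes(
    image: np.ndarray,
    method: str = "classical",
    external_map: np.ndarray | None = None,
    ridge_sigma: float = 1.0,
    background_sigma: float = 8.0,
) -> np.ndarray:
    """Per-pixel membrane probability in [0, 1].

    ``method="external"`` validates and returns a user-supplied map (e.g. the
    output of a trained membrane-segmentation network).  ``"classical"``
    computes a dark-ridge response: inverted intensity, band-pass smoothed
    (difference of Gaussians), clipped and rescaled to [0, 1].
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale section image")
    if method == "external":
        if external_map is None:
            raise ValueError("method 'external' requires an external probability map")
        ext = np.asarray(external_map, dtype=np.float64)
        if ext.shape != image.shape:
            raise ValueError(
                f"external map geometry {ext.shape} does not match image {image.shape}"
            )
        if not np.all(np.isfinite(ext)) or ext.min() < 0 or ext.max() > 1:
            raise ValueError("external probability map must be finite and within [0, 1]")
        return ext
    if method != "classical":
        raise ValueError(f"unknown membrane segmentation method: {method!r}")

    img = image.astype(np.float64)
    span = img.max() - img.min()
    inv = (img.max() - img) / span if span > 0 else np.zeros_like(img)
    response = gaussian(inv, ridge_sigma) - gaussian(inv, background_sigma)
    response = np.clip(response, 0.0, None)
    peak = response.max()
    return response / peak if peak > 0 else response


def watershed_regions(
    membranes: np.ndarray, h: float = DEFAULT_H_MINIMA
) -> np.ndarray:
    """Watershed of the membrane map from h-minima-suppressed minima seeds.

    Seeds are the regional minima after suppressing minima shallower than
    ``h``; watershed lines get label 0 and positive labels are contiguous
    from 1.  Deterministic for fixed input.
    """
    prob = np.asarray(membranes, dtype=np.float64)
    # h-minima suppression by grayscale reconstruction (erosion variant)
    from skimage.morphology import reconstruction

    filled = reconstruction(prob + h, prob, method="erosion")
    seeds = cc_label(local_minima(filled, connectivity=1), connectivity=1)
    if seeds.max() == 0:
        # no regional minima (e.g. constant map): one region covers the image
        return np.ones(prob.shape, dtype=np.int32)
    labels = watershed(prob, markers=seeds, connectivity=1, watershed_line=True)
    # relabel contiguously from 1
    out, _, _ = _relabel(labels)
    return out


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    mapping = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        mapping[old] = new
    return mapping[labels], ids, mapping


# --------------------------------------------------------------------------
# per-region contours and selection
# --------------------------------------------------------------------------

def region_boundary_radius(
    labels: np.ndarray,
    region_id: int,
    n_angles: int | None = None,
    max_empty_fraction: float = 0.25,
) -> Contour:
    """Boundary radius function of one labeled region about its centroid.

    Boundary pixels are binned by polar angle into ``n_angles`` equal bins;
    each bin's radius is the maximum boundary-point distance (penalizing
    lobes of non-star-convex shapes); empty bins are filled by circular
    linear interpolation.  When ``n_angles`` is None the bin count adapts to
    the boundary length (about two boundary pixels per bin, clamped to
    [48, 180]) so small regions keep their bins populated.  The contour's
    latitude is set to pi/2 (the equatorial convention used when scoring
    real image regions).
    """
    mask = np.asarray(labels) == region_id
    if not mask.any():
        raise ValueError(f"region {region_id} does not exist in the label map")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()

    interior = ndi.binary_erosion(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    by, bx = np.nonzero(mask & ~interior)
    ang = np.mod(np.arctan2(by - cy, bx - cx), 2 * np.pi)
    dist = np.hypot(by - cy, bx - cx)

    if n_angles is None:
        n_angles = int(np.clip(len(by) // 2, 48, DEFAULT_N_ANGLES))
    step = 2 * np.pi / n_angles
    bins = np.minimum((ang / step).astype(int), n_angles - 1)
    rho = np.full(n_angles, -np.inf)
    np.maximum.at(rho, bins, dist)
    rho[np.isinf(rho)] = np.nan

    empty = np.isnan(rho)
    if empty.mean() > max_empty_fraction:
        raise ValueError(
            f"region {region_id}: {empty.mean():.0%} of angular bins are empty "
            "(degenerate region)"
        )
    if empty.any():
        idx = np.arange(n_angles)
        good = ~empty
        # circular linear interpolation across the gap
        rho = np.interp(
            idx, idx[good], rho[good], period=n_angles
        )
    rho = np.maximum(rho, 1e-6)
    thetas = step * np.arange(n_angles)
    return Contour(angles=thetas, radii=rho, origin=(float(cx), float(cy)), latitude=np.pi / 2)


@dataclass
class RegionMask:
    """Binary mask of selected stable regions plus the per-region report."""

    mask: np.ndarray
    report: pd.DataFrame
    r_thres: float
    min_area: int

    @property
    def kept_labels(self) -> np.ndarray:
        return self.report.loc[self.report["kept"], "label"].to_numpy()


def select_regions(
    labels: np.ndarray,
    r_thres: float = DEFAULT_R_THRES,
    min_area: int = DEFAULT_MIN_AREA,
    n_angles: int | None = None,
    n_harm: int = DEFAULT_N_HARM,
    exclude_border: bool = True,
) -> RegionMask:
    """Keep regions whose boundary roundness index R is at least ``r_thres``.

    Every positive label is scored (Fourier spectrum of its boundary radius
    function, R = -log sum b_n); kept iff R >= r_thres, area >= min_area and
    (by default) the region does not touch the image border.  Returns the
    binary mask plus a full per-region report.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    rows = []
    mask = np.zeros(labels.shape, dtype=bool)
    for prop in regionprops(labels):
        lab = prop.label
        area = int(prop.area)
        cy, cx = prop.centroid
        row = {
            "label": lab,
            "area": area,
            "centroid_x": cx,
            "centroid_y": cy,
            "R": np.nan,
            "kept": False,
            "reason": "",
        }
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if area < min_area:
            row["reason"] = "too_small"
        elif exclude_border and touches:
            row["reason"] = "touches_border"
        else:
            try:
                contour = region_boundary_radius(labels, lab, n_angles=n_angles)
            except ValueError:
                row["reason"] = "degenerate"
            else:
                r_idx = contour_roundness(contour, n_harm=n_harm)
                row["R"] = r_idx.R
                if r_idx.R >= r_thres:
                    row["kept"] = True
                    row["reason"] = "kept"
                    mask |= labels == lab
                else:
                    row["reason"] = "below_R_thres"
        rows.append(row)
    columns = ["label", "area", "centroid_x", "centroid_y", "R", "kept", "reason"]
    report = pd.DataFrame(rows, columns=columns)
    return RegionMask(mask=mask, report=report, r_thres=r_thres, min_area=min_area)
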