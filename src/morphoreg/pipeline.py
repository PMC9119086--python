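"""Full-stack registration pipeline.

Per section: membrane segmentation -> watershed -> roundness-thresholded
region selection.  Per adjacent pair: dense descriptors -> discrete flow ->
grid correspondences inside the selected mask.  Whole stack: simultaneous
constrained displacement adjustment.  Per section: rigid-MLS warp by the
solved control-point displacements.  There is no reference section: the
aligned frame is fixed by the displacement-magnitude term of the stack
energy itself.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dense_correspondence import (
    FlowParams,
    dense_descriptors,
    grid_correspondences,
    match_flow,
)
from .phantom import ssim_score
from .region_selection import (
    DEFAULT_MIN_AREA,
    RegionMask,
    segment_membranes,
    select_regions,
    watershed_regions,
)
from .accuracy_theory import DEFAULT_R_THRES
from .stack_optimization import (
    CorrespondenceSet,
    DisplacementSolution,
    StackEnergyParams,
    solve_stack_displacements,
)
from .warp import ControlPointSet, mls_rigid_warp

logger = logging.getLogger("morphoreg")


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end registration pipeline."""

    segmentation_method: str = "classical"
    r_thres: float = DEFAULT_R_THRES
    min_area: int = DEFAULT_MIN_AREA
    flow: FlowParams = field(default_factory=FlowParams)
    grid_spacing: int = 16
    stack: StackEnergyParams = field(default_factory=StackEnergyParams)
    warp_grid_step: int = 8
    h_minima: float = 0.1
    #: optional phase-correlation translation pre-alignment (plumbing for
    #: stacks whose gross offsets exceed the flow search radius); OFF by default
    prealign: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flow = FlowParams(**raw.pop("flow", {}))
        stack = StackEnergyParams(**raw.pop("stack", {}))
        return cls(flow=flow, stack=stack, **raw)


@dataclass
class RegistrationResult:
    aligned: np.ndarray
    masks: list[RegionMask]
    correspondences: CorrespondenceSet
    solution: DisplacementSolution
    report: dict


def _section_mask(image, config: PipelineConfig, external_map=None) -> RegionMask:
    membranes = segment_membranes(
        image, method=config.segmentation_method, external_map=external_map
    )
    labels = watershed_regions(membranes, h=config.h_minima)
    return select_regions(labels, r_thres=config.r_thres, min_area=config.min_area)


def register_stack(
    images: np.ndarray,
    config: PipelineConfig | None = None,
    external_maps: np.ndarray | None = None,
) -> RegistrationResult:
    """Register a serial-section stack into a common frame.

    Parameters
    ----------
    images : (S, H, W) array
        Grayscale sections, uniform geometry, S >= 2.
    config : PipelineConfig
    external_maps : optional (S, H, W) array
        Membrane probability maps when ``segmentation_method == "external"``.

    Returns the aligned stack plus all intermediate artifacts and a report
    with per-stage timings, flow energies and the stack-energy residual.
    """
    if config is None:
        config = PipelineConfig()
    images = np.asarray(images)
    if images.ndim != 3 or images.shape[0] < 2:
        raise ValueError("expected an (S, H, W) stack with S >= 2")
    n_sections = images.shape[0]
    report: dict = {"stages": {}, "warnings": []}

    t0 = time.perf_counter()
    masks = []
    for s in range(n_sections):
        ext = external_maps[s] if external_maps is not None else None
        mask = _section_mask(images[s], config, ext)
        if not mask.mask.any():
            report["warnings"].append(
                f"section {s}: no region selected; falling back to full-image grid"
            )
            logger.warning("section %d: empty region mask, using full grid", s)
            mask.mask = np.ones(images[s].shape, dtype=bool)
        masks.append(mask)
    report["stages"]["region_selection_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    descriptors = [dense_descriptors(images[s]) for s in range(n_sections)]
    report["stages"]["descriptors_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pairs = []
    flow_energies = []
    for s in range(n_sections - 1):
        flow = match_flow(descriptors[s], descriptors[s + 1], config.flow)
        flow_energies.append(flow.energy)
        src, dst = grid_correspondences(flow, masks[s].mask, config.grid_spacing)
        if len(src) == 0:
            report["warnings"].append(
                f"pair {s}: no masked grid correspondences; using full grid"
            )
            src, dst = grid_correspondences(flow, None, config.grid_spacing)
        pairs.append((src, dst))
        logger.info("pair %d: %d correspondences, flow energy %.1f", s, len(src), flow.energy)
    corrs = CorrespondenceSet(pairs=pairs)
    report["stages"]["flow_s"] = time.perf_counter() - t0
    report["flow_energies"] = flow_energies

    t0 = time.perf_counter()
    solution = solve_stack_displacements(corrs, config.stack)
    report["stages"]["stack_optimization_s"] = time.perf_counter() - t0
    report["stack_energy"] = solution.energy
    report["max_constraint_residual"] = solution.max_constraint_residual

    t0 = time.perf_counter()
    aligned = np.empty_like(images, dtype=np.float32)
    max_disp = 0.0
    for s in range(n_sections):
        pts, disp = solution.section(s)
        if len(pts) == 0:
            aligned[s] = images[s].astype(np.float32)
            continue
        max_disp = max(max_disp, float(np.abs(disp).max()))
        cps = ControlPointSet(src=pts, dst=pts + disp)
        aligned[s] = mls_rigid_warp(images[s], cps, grid_step=config.warp_grid_step)
    report["stages"]["warp_s"] = time.perf_counter() - t0
    report["max_displacement_px"] = max_disp

    return RegistrationResult(
        aligned=aligned, masks=masks, correspondences=corrs,
        solution=solution, report=report,
    )


def registration_residuals(deformed_stack, result: RegistrationResult) -> dict:
    """Ground-truth correspondence residuals before and after registration.

    Evaluated at the correspondence source points the pipeline used: before
    registration the residual is the ground-truth displacement magnitude
    itself (identity estimate); after, it is the distance between the final
    positions of a point and of its true partner under each section's solved
    rigid-MLS motion.  Requires a stack with analytic ground truth
    (:class:`~morphoreg.phantom.PhantomStack`).
    """
    from .warp import mls_rigid_map

    h, w = deformed_stack.shape
    before, after = [], []
    for pair, (src, _dst) in enumerate(result.correspondences.pairs):
        if len(src) == 0:
            continue
        gt = deformed_stack.gt_point_flow(pair, src)
        partner = src + gt
        inside = np.all((partner >= 0) & (partner <= [w - 1, h - 1]), axis=1)
        if not inside.any():
            continue
        p, q = src[inside], partner[inside]
        before.append(np.linalg.norm(q - p, axis=1))
        pi, wi = result.solution.section(pair)
        pj, wj = result.solution.section(pair + 1)
        fi = mls_rigid_map(p, ControlPointSet(pi, pi + wi)) if len(pi) else p
        fj = mls_rigid_map(q, ControlPointSet(pj, pj + wj)) if len(pj) else q
        after.append(np.linalg.norm(fi - fj, axis=1))
    before = np.concatenate(before) if before else np.zeros(0)
    after = np.concatenate(after) if after else np.zeros(0)
    return {
        "n": int(before.size),
        "mean_before": float(before.mean()) if before.size else 0.0,
        "mean_after": float(after.mean()) if after.size else 0.0,
        "median_before": float(np.median(before)) if before.size else 0.0,
        "median_after": float(np.median(after)) if after.size else 0.0,
    }


def evaluate_alignment(aligned: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-section SSIM of an aligned stack vs ground truth and vs neighbors.

    One row per section: ``ssim_gt`` compares to the ground-truth section,
    ``ssim_adjacent`` to the next aligned section (NaN for the last row).
    """
    aligned = np.asarray(aligned)
    truth = np.asarray(truth)
    if aligned.shape != truth.shape:
        raise ValueError("aligned and truth stacks must have identical geometry")
    rows = []
    for s in range(aligned.shape[0]):
        ssim_adj = (
            ssim_score(aligned[s], aligned[s + 1]) if s + 1 < aligned.shape[0] else np.nan
        )
        rows.append(
            {"section": s, "ssim_gt": ssim_score(aligned[s], truth[s]), "ssim_adjacent": ssim_adj}
        )
    return pd.DataFrame(rows)
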