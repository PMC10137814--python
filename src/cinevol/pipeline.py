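"""End-to-end pixel-based measurement of a cine stack.

Reproduces the operator workflow headlessly: segment end-diastole (first
cine phase) from scripted brush strokes, find the basal slice via the 50 %
myocardial-ring rule, track the blood area of a mid-ventricular slice over
all phases to find end-systole, segment end-systole, and sum slice areas
into EDV/ESV via Simpson's rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .phantom import CineStack, PhantomTruth
from .segmentation import (
    BrushStroke,
    compute_local_stats,
    derive_bounds,
    plan_strokes,
    segment_strokes,
)
from .volumetry import (
    FunctionParams,
    compute_function_params,
    detect_basal_slice,
    included_slice_range,
    select_phases,
    simpson_volume,
)

__all__ = [
    "PbmMeasurement",
    "run_pbm",
    "phantom_stroke_planner",
    "intensity_myocardium_evidence",
]

StrokePlanner = Callable[[int, Optional[Sequence[int]]], list[BrushStroke]]
EvidenceProvider = Callable[[int], np.ndarray]


@dataclass
class PbmMeasurement:
    """Result of a pixel-based reading of one cine stack."""

    params: FunctionParams
    basal_slice_ed: int
    basal_slice_es: int
    mid_third_slice: int
    ed_phase: int
    es_phase: int
    mask_ed: np.ndarray
    mask_es: np.ndarray


def intensity_myocardium_evidence(
    stack: CineStack,
    phase: int,
    lo: float = 60.0,
    hi: float = 180.0,
) -> np.ndarray:
    """Myocardium evidence from an intensity window (slice, row, col)."""
    img = stack.intensities[:, phase]
    return (img >= lo) & (img <= hi)


def phantom_stroke_planner(
    stack: CineStack,
    truth: PhantomTruth,
    radius: int = 4,
    step: int = 2,
    k: float = 2.0,
) -> StrokePlanner:
    """Scripted operator for a phantom: brushes the true blood pool of each
    phase (the stand-in for a human roughly painting the cavity).

    Like a careful operator, it first samples the deepest blood pixel with
    the brush to fix intensity thresholds for the touch-up work in channels
    too narrow for single-tissue statistics.
    """

    def planner(phase: int, slices: Optional[Sequence[int]] = None) -> list[BrushStroke]:
        mask = truth.blood_masks[:, phase]
        bounds = None
        depth = [ndimage.distance_transform_edt(m) if m.any() else np.zeros(m.shape)
                 for m in mask]
        best_slice = int(np.argmax([d.max() for d in depth]))
        if depth[best_slice].max() > radius:
            r, c = np.unravel_index(int(np.argmax(depth[best_slice])),
                                    depth[best_slice].shape)
            stats = compute_local_stats(stack.intensities[best_slice, phase],
                                        (int(r), int(c)), radius)
            bounds = derive_bounds(stats, k=k)
        return plan_strokes(mask, radius=radius, step=step, slices=slices,
                            touchup_bounds=bounds)

    return planner


def run_pbm(
    stack: CineStack,
    stroke_planner: StrokePlanner,
    myocardium_evidence: EvidenceProvider | None = None,
    k: float = 2.0,
    closing_radius: int = 1,
    include_gap: bool = True,
    method_label: str = "PbM",
) -> PbmMeasurement:
    """Measure EDV/ESV/SV/EF of a cine stack with the pixel-based method.

    ``stroke_planner(phase, slices)`` supplies the brush strokes for a phase
    (optionally restricted to given slices); ``myocardium_evidence(phase)``
    supplies a (slice, row, col) myocardium mask for the basal-slice rule
    (defaults to an intensity window on the stack).
    """
    if myocardium_evidence is None:
        myocardium_evidence = lambda p: intensity_myocardium_evidence(stack, p)  # noqa: E731

    geometry = stack.geometry
    ed_phase = 0
    mask_ed = segment_strokes(stack, stroke_planner(ed_phase, None), phase=ed_phase,
                              k=k, closing_radius=closing_radius)
    basal_ed = detect_basal_slice(myocardium_evidence(ed_phase), mask_ed)
    included_ed = included_slice_range(mask_ed, basal_ed)
    if not included_ed:
        raise ValueError("no non-empty slices below the basal slice at ED")
    mid = basal_ed + len(included_ed) // 2

    # blood area of the mid-third slice across all phases -> end-systole
    n_phases = stack.n_phases
    mid_masks = np.zeros((n_phases,) + stack.intensities.shape[2:], dtype=bool)
    mid_masks[ed_phase] = mask_ed[mid]
    for p in range(n_phases):
        if p == ed_phase:
            continue
        strokes = stroke_planner(p, [mid])
        if strokes:
            mid_masks[p] = segment_strokes(stack, strokes, phase=p, k=k,
                                           closing_radius=closing_radius)[mid]
    _, es_phase = select_phases(mid_masks, mid)

    mask_es = segment_strokes(stack, stroke_planner(es_phase, None), phase=es_phase,
                              k=k, closing_radius=closing_radius)
    basal_es = detect_basal_slice(myocardium_evidence(es_phase), mask_es)

    pix = geometry.pixel_area
    areas_ed = [float(mask_ed[i].sum()) * pix for i in included_ed]
    included_es = included_slice_range(mask_es, basal_es)
    areas_es = [float(mask_es[i].sum()) * pix for i in included_es]
    edv = simpson_volume(areas_ed, geometry, include_gap=include_gap)
    esv = simpson_volume(areas_es, geometry, include_gap=include_gap)
    params = compute_function_params(edv, esv, method=method_label)
    return PbmMeasurement(
        params=params,
        basal_slice_ed=basal_ed,
        basal_slice_es=basal_es,
        mid_third_slice=mid,
        ed_phase=ed_phase,
        es_phase=es_phase,
        mask_ed=mask_ed,
        mask_es=mask_es,
    )
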