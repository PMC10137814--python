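"""Mask-level emulation of contour-surface (disc summation) references.

A human-drawn endocardial contour encloses the papillary muscles together
with the blood pool; at mask level that is the hole-filled union of blood
and papillary masks.  Commercial tools that report a papillary volume only
segment the part of the muscle that is free in the lumen, not the part
directly adjacent to the myocardium; here "adjacent" means in-plane
4-connectivity, per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ImageGeometry, PhantomTruth
from .volumetry import FunctionParams, compute_function_params, simpson_volume

__all__ = [
    "endocardial_fill",
    "luminal_papillary_volume",
    "filled_volume",
    "ReferenceResult",
    "reference_from_truth",
]

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def endocardial_fill(blood_mask: np.ndarray, papillary_mask: np.ndarray) -> np.ndarray:
    """The endocardium-enclosed region of one slice: blood and papillary
    muscle united, with interior holes filled."""
    blood_mask = np.asarray(blood_mask, dtype=bool)
    papillary_mask = np.asarray(papillary_mask, dtype=bool)
    if blood_mask.shape != papillary_mask.shape:
        raise ValueError("masks must be aligned")
    return ndimage.binary_fill_holes(blood_mask | papillary_mask)


def filled_volume(
    blood_masks: np.ndarray,
    papillary_masks: np.ndarray,
    geometry: ImageGeometry,
    include_gap: bool = True,
) -> float:
    """Contour-method volume (mL) of a 3D (slice, row, col) mask pair."""
    areas = [
        float(endocardial_fill(b, p).sum()) * geometry.pixel_area
        for b, p in zip(blood_masks, papillary_masks)
    ]
    return simpson_volume(areas, geometry, include_gap=include_gap)


def luminal_papillary_volume(
    papillary_masks: np.ndarray,
    myocardium_masks: np.ndarray,
    geometry: ImageGeometry,
    include_gap: bool = True,
) -> float:
    """Volume (mL) of papillary components with no pixel 4-adjacent to the
    myocardium — what a lumen-only automatic segmentation reports.

    Accepts 2D single slices or 3D (slice, row, col) stacks.
    """
    papillary_masks = np.asarray(papillary_masks, dtype=bool)
    myocardium_masks = np.asarray(myocardium_masks, dtype=bool)
    if papillary_masks.shape != myocardium_masks.shape:
        raise ValueError("masks must be aligned")
    if papillary_masks.ndim == 2:
        papillary_masks = papillary_masks[None]
        myocardium_masks = myocardium_masks[None]
    areas = []
    for pap, myo in zip(papillary_masks, myocardium_masks):
        labels, n = ndimage.label(pap, structure=_FOUR_CONN)
        luminal_px = 0
        for lab in range(1, n + 1):
            comp = labels == lab
            touch = ndimage.binary_dilation(comp, structure=_FOUR_CONN) & myo
            if not touch.any():
                luminal_px += int(comp.sum())
        areas.append(luminal_px * geometry.pixel_area)
    return simpson_volume(areas, geometry, include_gap=include_gap)


@dataclass(frozen=True)
class ReferenceResult:
    """Contour-method emulation on ground-truth masks of one phantom."""

    kfm: FunctionParams
    blood_only: FunctionParams
    papillary_enclosed_ed_ml: float
    papillary_enclosed_es_ml: float
    luminal_papillary_ed_ml: float
    luminal_papillary_es_ml: float


def reference_from_truth(
    truth: PhantomTruth,
    geometry: ImageGeometry,
    include_gap: bool = True,
) -> ReferenceResult:
    """Emulate the contour-surface reading of a phantom from its truth masks.

    The contour (KfM-like) volumes are hole-filled blood+papillary volumes at
    the true ED and ES phases; ``blood_only`` is the ideal pixel-based
    reading of the same masks.  The enclosed papillary volumes make the
    contour-minus-pixel identity checkable exactly.
    """
    ed, es = truth.ed_phase_index, truth.es_phase_index
    out = {}
    for name, phase in (("ed", ed), ("es", es)):
        blood = truth.blood_masks[:, phase]
        pap = truth.papillary_masks[:, phase]
        myo = truth.myocardium_masks[:, phase]
        filled = filled_volume(blood, pap, geometry, include_gap)
        blood_v = simpson_volume(
            [float(b.sum()) * geometry.pixel_area for b in blood], geometry, include_gap
        )
        out[name] = {
            "filled": filled,
            "blood": blood_v,
            "enclosed": filled - blood_v,
            "luminal": luminal_papillary_volume(pap, myo, geometry, include_gap),
        }
    kfm = compute_function_params(out["ed"]["filled"], out["es"]["filled"], method="KfM")
    pbm = compute_function_params(out["ed"]["blood"], out["es"]["blood"], method="PbM")
    return ReferenceResult(
        kfm=kfm,
        blood_only=pbm,
        papillary_enclosed_ed_ml=out["ed"]["enclosed"],
        papillary_enclosed_es_ml=out["es"]["enclosed"],
        luminal_papillary_ed_ml=out["ed"]["luminal"],
        luminal_papillary_es_ml=out["es"]["luminal"],
    )
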