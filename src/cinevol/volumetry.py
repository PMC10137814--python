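"""From per-slice masks to cardiac function parameters.

The measurement convention follows the clinical short-axis workflow: the
most basal included slice is the first one (counting from the atrial side)
whose myocardial ring is at least 50 % closed around the blood pool;
end-diastole is the first cine phase; end-systole is the phase with the
smallest blood-pool area on a mid-ventricular slice; slice areas are summed
with the inter-slice spacing (Simpson's rule) into volumes, from which
stroke volume SV = EDV - ESV and ejection fraction EF = SV / EDV follow.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .phantom import ImageGeometry

__all__ = [
    "BasalSliceError",
    "FunctionParams",
    "myocardial_ring_coverage",
    "detect_basal_slice",
    "select_phases",
    "mask_area",
    "simpson_volume",
    "compute_function_params",
    "included_slice_range",
]


class BasalSliceError(ValueError):
    """No slice of the stack has a sufficiently closed myocardial ring."""


@dataclass(frozen=True)
class FunctionParams:
    """Left-ventricular function parameters for one subject and method.

    ``ef`` is stored as a fraction; use :attr:`ef_pct` for display.
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef: float
    method: str = "PbM"

    def __post_init__(self) -> None:
        if not (self.edv_ml >= self.esv_ml >= 0):
            raise ValueError("require EDV >= ESV >= 0")
        if abs(self.sv_ml - (self.edv_ml - self.esv_ml)) > 1e-9 * max(1.0, self.edv_ml):
            raise ValueError("SV must equal EDV - ESV")

    @property
    def ef_pct(self) -> float:
        return 100.0 * self.ef

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "edv_ml": self.edv_ml,
            "esv_ml": self.esv_ml,
            "sv_ml": self.sv_ml,
            "ef": self.ef,
            "ef_pct": self.ef_pct,
        }


def compute_function_params(edv_ml: float, esv_ml: float, method: str = "PbM") -> FunctionParams:
    """SV = EDV - ESV and EF = SV / EDV from the two measured volumes."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    if esv_ml < 0:
        raise ValueError("ESV must be non-negative")
    if esv_ml > edv_ml:
        raise ValueError("ESV exceeds EDV: ED/ES phases are likely mislabelled")
    sv = edv_ml - esv_ml
    return FunctionParams(edv_ml=edv_ml, esv_ml=esv_ml, sv_ml=sv, ef=sv / edv_ml, method=method)


def mask_area(mask: np.ndarray, geometry: ImageGeometry) -> float:
    """Area of a binary 2D mask in mm^2 (pixel count x pixel area)."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * geometry.pixel_area


def simpson_volume(
    areas_mm2: Sequence[float],
    geometry: ImageGeometry,
    include_gap: bool = True,
) -> float:
    """Stack areas into a volume (mL) using Simpson's slice summation.

    Each slice contributes its area times the inter-slice spacing, which by
    default includes the acquisition gap (tissue in the gap contributes
    volume); ``include_gap=False`` uses the bare slice thickness.
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size and areas.min() < 0:
        raise ValueError("slice areas must be non-negative")
    spacing = geometry.slice_spacing if include_gap else geometry.slice_thickness
    return float(areas.sum() * spacing / 1000.0)


def myocardial_ring_coverage(
    myocardium: np.ndarray,
    blood: np.ndarray,
    n_bins: int = 360,
    r_outer_factor: float = 3.0,
) -> float:
    """Fraction of 360 angular bins around the blood-pool centroid in which
    myocardial evidence occurs.

    Myocardium pixels inside the blood pool are ignored, and only pixels
    within ``r_outer_factor`` times the blood pool's maximal radius count, so
    distant structures cannot close the ring.
    """
    blood = np.asarray(blood, dtype=bool)
    myocardium = np.asarray(myocardium, dtype=bool)
    if not blood.any():
        raise ValueError("blood mask is empty; slice is not a candidate")
    br, bc = np.nonzero(blood)
    cy, cx = br.mean(), bc.mean()
    r_blood = float(np.hypot(br - cy, bc - cx).max())
    r_outer = r_outer_factor * max(r_blood, 1.0)
    mr, mc = np.nonzero(myocardium & ~blood)
    if mr.size == 0:
        return 0.0
    dy, dx = mr - cy, mc - cx
    dist = np.hypot(dy, dx)
    sel = (dist > 0) & (dist <= r_outer)
    if not sel.any():
        return 0.0
    ang = np.arctan2(dy[sel], dx[sel]) % (2.0 * np.pi)
    # each pixel blocks the angular interval it subtends (half-diagonal wide),
    # so a closed digital ring yields full coverage at any resolution
    half_width = np.arctan2(math.sqrt(0.5), dist[sel])
    width = 2.0 * np.pi / n_bins
    occupied = np.zeros(n_bins, dtype=bool)
    b0 = np.floor((ang - half_width) / width).astype(int)
    b1 = np.floor((ang + half_width) / width).astype(int)
    for lo_b, hi_b in zip(b0, b1):
        occupied[np.arange(lo_b, hi_b + 1) % n_bins] = True
    return float(occupied.mean())


def detect_basal_slice(
    myocardium_evidence: np.ndarray,
    blood_masks: np.ndarray,
    threshold: float = 0.5,
) -> int:
    """Most basal slice whose myocardial ring is at least 50 % closed.

    Scans from slice 0 (atrial side) toward the apex; slices with an empty
    blood mask are not candidates.  Raises :class:`BasalSliceError` when no
    slice qualifies.
    """
    myocardium_evidence = np.asarray(myocardium_evidence, dtype=bool)
    blood_masks = np.asarray(blood_masks, dtype=bool)
    if myocardium_evidence.shape != blood_masks.shape:
        raise ValueError("evidence and blood masks must be aligned")
    for i in range(blood_masks.shape[0]):
        if not blood_masks[i].any():
            continue
        if myocardial_ring_coverage(myocardium_evidence[i], blood_masks[i]) >= threshold:
            return i
    raise BasalSliceError("no slice reaches 50% myocardial ring closure")


def select_phases(
    blood_masks: np.ndarray,
    mid_third_slice: int,
    geometry: Optional[ImageGeometry] = None,
) -> tuple[int, int]:
    """(ED, ES) phase indices: ED is the first cine image; ES is the phase
    with the smallest blood area on the given mid-ventricular slice (ties go
    to the lowest phase index).

    ``blood_masks`` is (slice, phase, row, col) or (phase, row, col) already
    restricted to the mid-third slice.
    """
    blood_masks = np.asarray(blood_masks, dtype=bool)
    if blood_masks.ndim == 4:
        per_phase = blood_masks[mid_third_slice]
    elif blood_masks.ndim == 3:
        per_phase = blood_masks
    else:
        raise ValueError("blood_masks must be 3D (phase, row, col) or 4D")
    if per_phase.shape[0] < 2:
        raise ValueError("need at least 2 phases")
    areas = per_phase.reshape(per_phase.shape[0], -1).sum(axis=1)
    if not areas.any():
        raise ValueError("blood area is empty in every phase on the mid-third slice")
    return 0, int(np.argmin(areas))


def included_slice_range(blood_masks_3d: np.ndarray, basal: int) -> list[int]:
    """Slices entering Simpson summation: from the basal slice to the last
    non-empty slice toward the apex (trailing empty slices are excluded)."""
    blood_masks_3d = np.asarray(blood_masks_3d, dtype=bool)
    nonempty = [i for i in range(basal, blood_masks_3d.shape[0]) if blood_masks_3d[i].any()]
    if not nonempty:
        return []
    return list(range(basal, nonempty[-1] + 1))
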