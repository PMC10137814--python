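"""Headless pixel-based brush segmentation.

The interactive tool this module reproduces lets an operator roughly paint
the blood pool with a brush.  At every cursor position the local intensity
statistics (minimum, maximum, mean, variance) inside the brush disk are
computed, an intensity window is derived from them (mean +/- k sigma, clipped
to the observed local range, or a fixed user window), and a 4-connected
region growth from the cursor position is performed inside the brush disk and
the window.  The union over all cursor positions of a stroke, followed by a
morphological closing that fills pixel-scale noise holes, is the resulting
blood-pool mask for that slice.

All operations are strictly 2D per slice, mirroring the slice-wise workflow.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing
from skimage.morphology import disk

from .phantom import CineStack

__all__ = [
    "BrushStroke",
    "LocalStats",
    "OutOfBoundsSeedWarning",
    "brush_disk_mask",
    "compute_local_stats",
    "derive_bounds",
    "region_grow",
    "apply_closing",
    "segment_stroke",
    "segment_strokes",
    "plan_strokes",
]

logger = logging.getLogger(__name__)

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


class OutOfBoundsSeedWarning(UserWarning):
    """A cursor position's intensity fell outside the active window (the
    operator painted non-blood tissue); its contribution is empty."""


@dataclass(frozen=True)
class LocalStats:
    """Intensity statistics of a brush neighbourhood."""

    minimum: float
    maximum: float
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("require minimum <= mean <= maximum")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(frozen=True)
class BrushStroke:
    """A scripted brush stroke: ordered cursor positions plus brush radius.

    ``positions`` are 0-based (slice, row, col) integer triples; ``radius``
    is the brush radius in pixels; ``fixed_bounds`` optionally replaces the
    locally derived intensity window entirely.
    """

    positions: tuple[tuple[int, int, int], ...]
    radius: int
    fixed_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("brush radius must be >= 1 pixel")
        object.__setattr__(
            self, "positions", tuple((int(s), int(r), int(c)) for s, r, c in self.positions)
        )
        if self.fixed_bounds is not None:
            lo, hi = self.fixed_bounds
            if lo > hi:
                raise ValueError("fixed_bounds must satisfy lo <= hi")
            object.__setattr__(self, "fixed_bounds", (float(lo), float(hi)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "radius": self.radius,
            "positions": [list(p) for p in self.positions],
            "fixed_bounds": list(self.fixed_bounds) if self.fixed_bounds else None,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BrushStroke":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        fb = payload.get("fixed_bounds")
        return cls(
            positions=tuple(tuple(p) for p in payload["positions"]),
            radius=int(payload["radius"]),
            fixed_bounds=tuple(fb) if fb else None,
        )


def brush_disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    """Boolean mask of pixels whose centre lies within ``radius`` (Euclidean,
    in pixel units) of ``center``, clipped to the image."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def compute_local_stats(image: np.ndarray, position: tuple[int, int], radius: int) -> LocalStats:
    """Min/max/mean/variance of the brush neighbourhood around ``position``.

    The neighbourhood is the Euclidean disk of the given pixel radius,
    clipped to the image bounds.  Variance is the population variance of the
    in-disk intensities.
    """
    image = np.asarray(image, dtype=float)
    r, c = position
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"position {position} outside image of shape {image.shape}")
    disk_m = brush_disk_mask(image.shape, (r, c), radius)
    vals = image[disk_m]
    return LocalStats(
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        mean=float(vals.mean()),
        variance=float(vals.var()),
    )


def derive_bounds(
    stats: LocalStats,
    k: float = 2.0,
    fixed_bounds: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Intensity window from local statistics: mean +/- k sigma, clipped to
    the locally observed [min, max]; a fixed window overrides entirely."""
    if fixed_bounds is not None:
        return (float(fixed_bounds[0]), float(fixed_bounds[1]))
    if k <= 0:
        raise ValueError("k must be positive")
    sigma = float(np.sqrt(stats.variance))
    lo = max(stats.minimum, stats.mean - k * sigma)
    hi = min(stats.maximum, stats.mean + k * sigma)
    return (lo, hi)


def region_grow(
    image: np.ndarray,
    seed: tuple[int, int],
    bounds: tuple[float, float],
    brush_disk: np.ndarray,
) -> np.ndarray:
    """4-connected component of in-window pixels inside the brush disk that
    contains the seed.  A seed outside the window yields an empty mask and a
    warning (the operator painted non-blood tissue)."""
    image = np.asarray(image, dtype=float)
    lo, hi = bounds
    allowed = (image >= lo) & (image <= hi) & brush_disk
    r, c = seed
    if not allowed[r, c]:
        warnings.warn(
            f"seed at {seed} (intensity {image[r, c]:.1f}) outside window "
            f"[{lo:.1f}, {hi:.1f}]; empty contribution",
            OutOfBoundsSeedWarning,
            stacklevel=2,
        )
        return np.zeros(image.shape, dtype=bool)
    labels, _ = ndimage.label(allowed, structure=_FOUR_CONN)
    return labels == labels[r, c]


def apply_closing(mask: np.ndarray, element_radius: int = 1) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a disk element,
    applied per 2D slice over the last two axes."""
    mask = np.asarray(mask, dtype=bool)
    if element_radius < 1:
        return mask.copy()
    footprint = disk(element_radius)
    if mask.ndim == 2:
        return _closing(mask, footprint)
    out = np.empty_like(mask)
    for idx in np.ndindex(mask.shape[:-2]):
        out[idx] = _closing(mask[idx], footprint)
    return out


def _grow_union(
    stack: CineStack,
    stroke: BrushStroke,
    phase: int,
    k: float,
) -> np.ndarray:
    """Pre-closing union of per-position region growths for one phase."""
    shape = stack.intensities.shape
    out = np.zeros((shape[0], shape[2], shape[3]), dtype=bool)
    for s, r, c in stroke.positions:
        if not (0 <= s < shape[0]):
            raise ValueError(f"stroke position slice {s} outside stack")
        image = stack.intensities[s, phase]
        if not (0 <= r < shape[2] and 0 <= c < shape[3]):
            raise ValueError(f"stroke position {(s, r, c)} outside image")
        if stroke.fixed_bounds is not None:
            bounds = stroke.fixed_bounds
        else:
            bounds = derive_bounds(compute_local_stats(image, (r, c), stroke.radius), k=k)
        disk_m = brush_disk_mask(image.shape, (r, c), stroke.radius)
        out[s] |= region_grow(image, (r, c), bounds, disk_m)
    return out


def segment_stroke(
    stack: CineStack,
    stroke: BrushStroke,
    phase: int = 0,
    k: float = 2.0,
    closing_radius: int = 1,
) -> np.ndarray:
    """Segment one cine phase from a brush stroke.

    Returns a (slice, row, col) boolean mask: the union over all cursor
    positions of the in-disk, in-window region growths, followed by a
    per-slice morphological closing.  Deterministic for a fixed stroke.
    """
    return apply_closing(_grow_union(stack, stroke, phase, k), closing_radius)


def segment_strokes(
    stack: CineStack,
    strokes: Sequence[BrushStroke],
    phase: int = 0,
    k: float = 2.0,
    closing_radius: int = 1,
) -> np.ndarray:
    """Union of several strokes (e.g. different brush radii) before closing."""
    shape = stack.intensities.shape
    out = np.zeros((shape[0], shape[2], shape[3]), dtype=bool)
    for stroke in strokes:
        out |= _grow_union(stack, stroke, phase, k)
    return apply_closing(out, closing_radius)


def plan_strokes(
    target: np.ndarray,
    radius: int = 4,
    step: int = 2,
    slices: Optional[Sequence[int]] = None,
    touchup_bounds: Optional[tuple[float, float]] = None,
) -> list[BrushStroke]:
    """Script a brush stroke that paints a target mask, as an operator would.

    Cursor positions are pixels whose full brush disk lies inside the target,
    so the local statistics at every position are single-tissue; boundary
    pixels are reached by the disks, not by seeding on them.  A serpentine
    grid of spacing ``step`` is used, densified where its disks would leave
    target pixels uncovered.  Where the target is too thin for the requested
    radius the per-slice radius shrinks (fine apex brushwork); 1-2 pixel
    pools are painted pixel by pixel with the smallest brush.

    Parameters
    ----------
    target : (slice, row, col) boolean array
        The region the scripted operator intends to paint.
    touchup_bounds : (lo, hi), optional
        Fixed intensity window for the last-resort positions in channels too
        narrow for any single-tissue brush (the operator setting fixed
        thresholds from a blood sample before painting the tricky spots).
        Without it those positions fall back to locally derived bounds.
    """
    target = np.asarray(target, dtype=bool)
    if target.ndim != 3:
        raise ValueError("target must be 3D (slice, row, col)")
    by_radius: dict[int, list[tuple[int, int, int]]] = {}
    rest_positions: list[tuple[int, int, int]] = []
    slice_range = range(target.shape[0]) if slices is None else slices
    for s in slice_range:
        m = target[s]
        if not m.any():
            continue
        edt = ndimage.distance_transform_edt(m)
        r_eff = radius
        while r_eff > 1 and not np.any(edt > r_eff):
            r_eff -= 1
        eligible = edt > r_eff
        if not eligible.any():
            eligible = m  # tiny pool: paint every pixel with the smallest brush
            r_eff = 1
        rows, cols = np.nonzero(eligible)
        keep = ((rows - rows.min()) % step == 0) & ((cols - cols.min()) % step == 0)
        if not keep.any():
            keep = np.ones(rows.shape, dtype=bool)
        pos_mask = np.zeros_like(m)
        pos_mask[rows[keep], cols[keep]] = True
        covered = ndimage.binary_dilation(pos_mask, structure=disk(r_eff).astype(bool))
        pr, pc = np.nonzero(pos_mask)
        by_radius.setdefault(r_eff, []).extend(
            (s, r, c) for r, c in _serpentine(pr, pc)
        )
        # fine pass: radius-1 brushwork from interior pixels next to anything
        # the coarse disks missed (narrow channels along the papillary
        # muscles, staircase boundary corners, apex)
        uncovered = m & ~covered
        fine = (edt > 1) & ndimage.binary_dilation(
            uncovered, structure=_FOUR_CONN
        )
        if fine.any():
            covered |= ndimage.binary_dilation(fine, structure=disk(1).astype(bool))
            fr, fc = np.nonzero(fine)
            by_radius.setdefault(1, []).extend(
                (s, r, c) for r, c in _serpentine(fr, fc)
            )
        # last resort: paint stranded boundary pixels directly
        rest = m & ~covered
        if rest.any():
            rr_, rc_ = np.nonzero(rest)
            rest_positions.extend((s, int(r), int(c)) for r, c in zip(rr_, rc_))
    strokes = [
        BrushStroke(positions=tuple(pos), radius=r)
        for r, pos in sorted(by_radius.items(), reverse=True)
    ]
    if rest_positions:
        strokes.append(
            BrushStroke(positions=tuple(rest_positions), radius=1,
                        fixed_bounds=touchup_bounds)
        )
    return strokes


def _serpentine(rows: np.ndarray, cols: np.ndarray) -> list[tuple[int, int]]:
    """Order grid positions row by row, alternating direction (a brush path)."""
    order: list[tuple[int, int]] = []
    flip = False
    for r in np.unique(rows):
        cs = np.sort(cols[rows == r])
        if flip:
            cs = cs[::-1]
        order.extend((int(r), int(c)) for c in cs)
        flip = not flip
    return order
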