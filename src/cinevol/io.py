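"""File formats: NIfTI cine stacks and masks, JSON/CSV results.

Cine stacks are interchanged as 4D NIfTI (row, col, slice, phase on disk;
in memory the package indexes (slice, phase, row, col)).  Pixel spacings and
the slice centre-to-centre distance live in the NIfTI header; the split of
that distance into slice thickness and gap fraction cannot be expressed in a
NIfTI header, so it travels in a small JSON sidecar next to the image.  All
result serialisations are deterministic (sorted keys, fixed float format).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import CineStack, ImageGeometry, PhantomTruth
from .volumetry import FunctionParams

__all__ = [
    "read_cine",
    "write_cine",
    "read_mask",
    "write_mask",
    "write_params",
    "read_params",
    "write_truth",
    "write_json",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".geom.json")
    return path.with_suffix(".geom.json")


def _to_disk_order(array_spr: np.ndarray) -> np.ndarray:
    # (slice, phase, row, col) -> (row, col, slice, phase)
    return np.transpose(array_spr, (2, 3, 0, 1))


def _from_disk_order(array_disk: np.ndarray) -> np.ndarray:
    return np.transpose(array_disk, (2, 3, 0, 1))


def write_cine(path: str | Path, stack: CineStack) -> Path:
    """Write a cine stack as 4D NIfTI plus a geometry sidecar JSON."""
    path = Path(path)
    g = stack.geometry
    affine = np.diag([g.spacing_row, g.spacing_col, g.slice_spacing, 1.0])
    img = nib.Nifti1Image(
        _to_disk_order(stack.intensities).astype(np.float32), affine
    )
    img.header.set_zooms((g.spacing_row, g.spacing_col, g.slice_spacing, 1.0))
    nib.save(img, path)
    sidecar = {
        "slice_thickness": g.slice_thickness,
        "gap_fraction": g.gap_fraction,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    return path


def read_cine(path: str | Path, gap_fraction: float | None = None) -> CineStack:
    """Read a 4D NIfTI cine stack.

    Spacings come from the header; slice thickness and gap fraction come
    from the sidecar when present, else the header slice spacing is taken as
    the thickness with ``gap_fraction`` (default 0) on top.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"{path} is {data.ndim}D; a cine stack needs 4 dimensions "
            "(row, col, slice, phase) — the phase axis is missing"
        )
    # zooms are float32 in the header; round away representation noise
    zooms = [round(float(z), 6) for z in img.header.get_zooms()[:3]]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path} has non-positive voxel spacings {zooms}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        thickness = float(meta["slice_thickness"])
        gap = float(meta["gap_fraction"])
    else:
        gap = float(gap_fraction or 0.0)
        thickness = float(zooms[2]) / (1.0 + gap)
    geometry = ImageGeometry(
        spacing_row=float(zooms[0]),
        spacing_col=float(zooms[1]),
        slice_thickness=thickness,
        gap_fraction=gap,
        n_slices=data.shape[2],
        n_phases=data.shape[3],
    )
    return CineStack(intensities=_from_disk_order(data).astype(float), geometry=geometry)


def write_mask(path: str | Path, mask: np.ndarray, geometry: ImageGeometry) -> Path:
    """Write a binary mask (3D slice-row-col or 4D slice-phase-row-col) as
    uint8 NIfTI aligned to its source stack."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        mask = mask[:, None]
    disk_arr = _to_disk_order(mask.astype(np.uint8))
    affine = np.diag([geometry.spacing_row, geometry.spacing_col,
                      geometry.slice_spacing, 1.0])
    nib.save(nib.Nifti1Image(disk_arr, affine), path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask`; returns (slice, phase,
    row, col) boolean (phase axis length 1 for 3D masks)."""
    data = np.asanyarray(nib.load(path).dataobj)
    if data.ndim == 3:
        data = data[..., None]
    return _from_disk_order(data) > 0


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    return path


def write_params(path: str | Path, params: FunctionParams) -> Path:
    return write_json(path, params.to_dict())


def read_params(path: str | Path) -> FunctionParams:
    payload = json.loads(Path(path).read_text())
    return FunctionParams(
        edv_ml=payload["edv_ml"],
        esv_ml=payload["esv_ml"],
        sv_ml=payload["sv_ml"],
        ef=payload["ef"],
        method=payload.get("method", "PbM"),
    )


def write_truth(directory: str | Path, truth: PhantomTruth, geometry: ImageGeometry) -> Path:
    """Write a phantom truth: JSON manifest plus per-class 4D mask NIfTIs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_json(directory / "truth_manifest.json", truth.to_manifest())
    write_mask(directory / "truth_blood.nii.gz", truth.blood_masks, geometry)
    write_mask(directory / "truth_papillary.nii.gz", truth.papillary_masks, geometry)
    write_mask(directory / "truth_myocardium.nii.gz", truth.myocardium_masks, geometry)
    return directory
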