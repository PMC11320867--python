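"""NIfTI and manifest I/O.

Masks and HU volumes are stored as 3D NIfTI images with a diagonal affine:
the array axes map directly to world axes, the affine diagonal carries the
voxel spacing and the translation column the center of voxel (0, 0, 0).
A *manifest* is a JSON file mapping image files to structure roles and
modalities, used by the command-line interface to assemble structure sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import MaskIOError
from .grids import BinaryStructure, HUVolume, ImageGrid, Modality


def _grid_from_img(img: nib.Nifti1Image, frame_id: str) -> ImageGrid:
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise MaskIOError("only axis-aligned (diagonal affine) NIfTI images are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise MaskIOError(f"non-positive voxel spacing in affine: {spacing}")
    shape = img.shape
    if len(shape) != 3:
        raise MaskIOError(f"expected a 3D image, got shape {shape}")
    return ImageGrid(
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
        shape=tuple(int(n) for n in shape),
        frame_id=frame_id,
    )


def _affine(grid: ImageGrid) -> np.ndarray:
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    return affine


def read_structure(
    path: str | Path, name: str, modality: Modality, frame_id: str = "unknown"
) -> BinaryStructure:
    """Read a binary mask from a 3D NIfTI file.

    Values must be restricted to {0, 1}; anything else raises
    :class:`~sctqa.errors.MaskIOError`.
    """
    img = nib.load(str(path))
    grid = _grid_from_img(img, frame_id)
    data = np.asanyarray(img.dataobj)
    if not np.isin(np.unique(data), (0, 1)).all():
        raise MaskIOError(f"{path}: mask values must be 0 or 1")
    return BinaryStructure(name=name, modality=modality, grid=grid, mask=data.astype(bool))


def write_structure(s: BinaryStructure, path: str | Path) -> None:
    img = nib.Nifti1Image(s.mask.astype(np.uint8), _affine(s.grid))
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: Modality, frame_id: str = "unknown") -> HUVolume:
    """Read an HU-valued 3D NIfTI volume."""
    img = nib.load(str(path))
    grid = _grid_from_img(img, frame_id)
    values = np.asanyarray(img.dataobj).astype(np.float32)
    return HUVolume(grid=grid, values=values, modality=modality)


def write_volume(v: HUVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.values, dtype=np.float32), _affine(v.grid))
    nib.save(img, str(path))


@dataclass
class ManifestEntry:
    path: str
    role: str
    modality: Modality
    kind: str = "mask"  # "mask" or "volume"


def load_manifest(path: str | Path, frame_id: str = "unknown") -> dict[str, BinaryStructure]:
    """Load all mask entries of a JSON manifest, keyed by role.

    The manifest is a JSON list of ``{"path", "role", "modality", "kind"}``
    objects; relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    entries = json.loads(path.read_text())
    out: dict[str, BinaryStructure] = {}
    for e in entries:
        if e.get("kind", "mask") != "mask":
            continue
        p = Path(e["path"])
        if not p.is_absolute():
            p = path.parent / p
        out[e["role"]] = read_structure(p, e["role"], e["modality"], frame_id=frame_id)
    return out


def save_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([e.__dict__ for e in entries], indent=2, sort_keys=True) + "\n"
    )
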