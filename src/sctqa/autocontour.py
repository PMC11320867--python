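"""HU-threshold auto-contouring of body, brain and bone.

Emulates the three treatment-planning-system behaviours used to generate
these structures from CT-like images:

* *search body* — global HU threshold, keep the largest connected
  component, fill internal cavities, smooth with one binary opening;
* *flood fill* — region growing from a seed over voxels whose HU lies
  within a "goodness" half-range of the seed value;
* *segmentation wizard* — a windowed initial segmentation around an
  organ-specific reference HU, clearing of axial planes far from the main
  segmented region, then a small physical dilation.

The vendor's exact post-processing filters and per-organ parameters are
proprietary and unpublished; the steps here are a documented emulation
calibrated on the synthetic phantom, not a replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import EmptyResultError, ValidationError
from .grids import BinaryStructure, HUVolume
from .margins import expand_isotropic

Organ = Literal["brain", "bone"]

#: Default body thresholds per modality: CT uses -350 HU, synthetic CT
#: (noisier air/tissue interface) -850 HU.
BODY_THRESHOLD_HU = {"CT": -350.0, "sCT": -850.0, "CBCT": -350.0}

_FACE = ndimage.generate_binary_structure(3, 1)
_FULL = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class AutoContourConfig:
    """Tunable parameters of the auto-contouring emulation.

    ``flood_goodness_hu`` is the HU half-range treated as "similar" during
    region growing; ``plane_clear_distance_mm`` removes axial planes
    farther than this from the main segmented region's plane range;
    ``dilation_mm`` is the wizard's final physical dilation. Reference HU
    values anchor the wizard's per-organ window.
    """

    body_threshold_hu: float = -350.0
    flood_goodness_hu: float = 300.0
    plane_clear_distance_mm: float = 10.0
    dilation_mm: float = 0.5
    connectivity: int = 6
    brain_reference_hu: float = 40.0
    bone_reference_hu: float = 1000.0

    def __post_init__(self) -> None:
        if self.flood_goodness_hu < 0:
            raise ValidationError("goodness must be non-negative")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")

    @property
    def _growth_structure(self) -> np.ndarray:
        return _FACE if self.connectivity == 6 else _FULL


def _largest_component(mask: np.ndarray, structure: np.ndarray = _FULL) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def search_body(v: HUVolume, threshold_hu: float | None = None) -> BinaryStructure:
    """Body contour by global HU threshold.

    Thresholds at ``>= threshold_hu`` (modality default if omitted), keeps
    the largest 26-connected component, fills internal cavities and applies
    one binary opening.
    """
    if threshold_hu is None:
        threshold_hu = BODY_THRESHOLD_HU.get(v.modality, -350.0)
    mask = v.values >= threshold_hu
    if not mask.any():
        raise EmptyResultError(f"no voxel above {threshold_hu} HU")
    mask = _largest_component(mask)
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_opening(mask, structure=_FACE)
    if not mask.any():
        raise EmptyResultError("body segmentation vanished during post-processing")
    return BinaryStructure(name="body", modality=v.modality, grid=v.grid, mask=mask)


def flood_fill(
    v: HUVolume,
    seed_index: tuple[int, int, int],
    goodness_hu: float,
    connectivity: int = 6,
) -> BinaryStructure:
    """Region growing from a seed voxel.

    Returns the connected region (6- or 26-connectivity) of voxels whose
    HU lies within ``goodness_hu`` of the seed's HU, containing the seed.
    """
    seed = tuple(int(i) for i in seed_index)
    for axis, i in enumerate(seed):
        if not 0 <= i < v.grid.shape[axis]:
            raise IndexError(f"seed {seed} outside volume shape {v.grid.shape}")
    if goodness_hu < 0:
        raise ValidationError("goodness must be non-negative")
    structure = _FACE if connectivity == 6 else _FULL
    similar = np.abs(v.values - v.values[seed]) <= goodness_hu
    labels, _ = ndimage.label(similar, structure=structure)
    return BinaryStructure(
        name="derived", modality=v.modality, grid=v.grid, mask=labels == labels[seed]
    )


def segmentation_wizard(
    v: HUVolume, organ: Organ, cfg: AutoContourConfig = AutoContourConfig()
) -> BinaryStructure:
    """Organ segmentation by HU window, plane clearing and dilation.

    The initial segmentation is the set of voxels within
    ``flood_goodness_hu`` of the organ's reference HU; its largest
    connected component (26-connectivity) is the main volume. Axial planes
    whose distance to the main volume's plane range exceeds
    ``plane_clear_distance_mm`` are cleared, which keeps satellite
    same-window components near the organ (e.g. detached bone-valued
    islands) while discarding remote ones. The surviving mask is dilated
    by ``dilation_mm``.
    """
    if organ == "brain":
        reference = cfg.brain_reference_hu
    elif organ == "bone":
        reference = cfg.bone_reference_hu
    else:
        raise ValidationError(f"unknown organ {organ!r}")

    window = np.abs(v.values - reference) <= cfg.flood_goodness_hu
    if not window.any():
        raise EmptyResultError(f"no voxel within {cfg.flood_goodness_hu} HU of {reference} HU")
    main = _largest_component(window)
    if organ == "brain":
        # The brain is a single region; satellite soft-tissue components
        # (scalp) share its HU window and must not be retained.
        window = main

    planes = np.flatnonzero(main.any(axis=(0, 1)))
    z_sp = v.grid.spacing[2]
    zmin, zmax = planes.min(), planes.max()
    z_idx = np.arange(v.grid.shape[2])
    dist_mm = np.maximum(zmin - z_idx, z_idx - zmax).clip(min=0) * z_sp
    keep = dist_mm <= cfg.plane_clear_distance_mm
    mask = window & keep[None, None, :]
    if not mask.any():
        raise EmptyResultError("segmentation empty after plane clearing")

    result = BinaryStructure(name=organ, modality=v.modality, grid=v.grid, mask=mask)
    if cfg.dilation_mm > 0:
        result = expand_isotropic(result, cfg.dilation_mm)
        result.name = organ
    return result
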