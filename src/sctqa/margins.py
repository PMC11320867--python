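"""Target-construction operators: margins, cropping and brain adjustment.

The planning target volume (PTV) is built from the clinical target volume
(CTV) by isotropic expansion in physical millimetres (3 mm by default).
Two CTV pathways exist when synthetic-CT bone carries surgical-fixation
artefacts:

* adjusted — the brain contour is extended up to ``brain_adjust_mm``
  (default 3.5 mm) into the sCT bone in the neighbourhood of the target,
  and the CTV is cropped to this adjusted brain (``CTV_a``);
* non-adjusted — the CTV is cropped against the sCT bone directly
  (``CTV_na``), accepting that artefact voxels are carved out of it.

Expansion is anisotropic-spacing-aware: a voxel joins the expanded mask iff
its center lies within the margin (Euclidean, mm) of some source voxel
center, evaluated with an exact Euclidean distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .grids import BinaryStructure, intersect, subtract, union

#: Absolute slack (mm) on the margin inclusion rule, guarding against
#: floating-point noise in the distance transform only.
_EDT_EPS = 1e-9


@dataclass(frozen=True)
class MarginPolicy:
    """Margin and brain-adjustment settings for target construction."""

    ptv_margin_mm: float = 3.0
    brain_adjust_mm: float = 3.5
    adjust_enabled: bool = True

    def __post_init__(self) -> None:
        if self.ptv_margin_mm < 0 or self.brain_adjust_mm < 0:
            raise ValidationError("margins must be non-negative")


def _bbox_slices(mask: np.ndarray, pad_voxels: tuple[int, int, int]) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad_voxels, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def expand_isotropic(s: BinaryStructure, margin_mm: float) -> BinaryStructure:
    """Expand a mask by an isotropic physical margin.

    The result is a superset of the input, clipped to the grid. The
    distance transform is evaluated on the mask's bounding box (padded by
    the margin) — outside that box no voxel can satisfy the inclusion rule.
    """
    if margin_mm < 0:
        raise ValidationError(f"margin must be non-negative, got {margin_mm}")
    if margin_mm == 0 or s.is_empty:
        return s.with_mask(s.mask.copy())

    spacing = np.asarray(s.grid.spacing)
    pad = tuple(int(np.ceil(margin_mm / sp)) + 1 for sp in spacing)
    box = _bbox_slices(s.mask, pad)
    sub = s.mask[box]
    dist = ndimage.distance_transform_edt(~sub, sampling=spacing)
    out = np.zeros_like(s.mask)
    out[box] = dist <= margin_mm + _EDT_EPS
    return s.with_mask(out)


def crop_ctv_to_brain(ctv: BinaryStructure, brain: BinaryStructure) -> BinaryStructure:
    """Crop the CTV to the brain (anatomical-barrier cropping)."""
    result = intersect(ctv, brain)
    return ctv.with_mask(result.mask)


def crop_ctv_against_bone(ctv: BinaryStructure, bone_sct: BinaryStructure) -> BinaryStructure:
    """Non-adjusted pathway: remove sCT bone (including any surgical-
    fixation artefact rendered as bone) from the CTV."""
    result = subtract(ctv, bone_sct)
    return ctv.with_mask(result.mask, name="CTV_na")


def adjust_brain(
    brain: BinaryStructure,
    bone_sct: BinaryStructure,
    target: BinaryStructure,
    adjust_mm: float,
) -> BinaryStructure:
    """Extend the brain contour into sCT bone near the target.

    Emulates the manual contouring step that reclaims brain tissue rendered
    as bone by a surgical-fixation-device artefact: the brain is grown by
    ``adjust_mm``, restricted to sCT bone, and restricted further to the
    ``adjust_mm`` neighbourhood of the target, then united with the
    original brain. With ``adjust_mm = 0`` or bone disjoint from the grown
    brain, the brain is returned unchanged.
    """
    brain.grid.require_compatible(bone_sct.grid)
    brain.grid.require_compatible(target.grid)
    if adjust_mm < 0:
        raise ValidationError(f"adjustment must be non-negative, got {adjust_mm}")
    if adjust_mm == 0:
        return brain.with_mask(brain.mask.copy())
    grown = expand_isotropic(brain, adjust_mm)
    near_target = expand_isotropic(target, adjust_mm)
    extension = intersect(intersect(grown, bone_sct), near_target)
    return brain.with_mask(union(brain, extension).mask)


def build_targets(
    ctv: BinaryStructure,
    brain: BinaryStructure,
    bone_sct: BinaryStructure,
    policy: MarginPolicy = MarginPolicy(),
) -> dict[str, BinaryStructure]:
    """Construct both CTV/PTV pathways from a raw CTV.

    Returns the adjusted brain plus ``CTV_a``/``PTV_a`` (CTV cropped to the
    adjusted brain, then expanded) and ``CTV_na``/``PTV_na`` (CTV cropped
    against sCT bone, then expanded).
    """
    brain_adj = adjust_brain(brain, bone_sct, ctv, policy.brain_adjust_mm)
    ctv_a = crop_ctv_to_brain(ctv, brain_adj)
    ctv_a.name = "CTV_a"
    ptv_a = expand_isotropic(ctv_a, policy.ptv_margin_mm)
    ptv_a.name = "PTV_a"
    ctv_na = crop_ctv_against_bone(ctv, bone_sct)
    ptv_na = expand_isotropic(ctv_na, policy.ptv_margin_mm)
    ptv_na.name = "PTV_na"
    return {
        "brain_adjusted": brain_adj,
        "CTV_a": ctv_a,
        "PTV_a": ptv_a,
        "CTV_na": ctv_na,
        "PTV_na": ptv_na,
    }
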