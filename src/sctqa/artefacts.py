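"""Surgical-fixation-device (SFD) artefact analysis.

Synthetic CT (sCT) images generated from MR render the signal void of a
clamp-style SFD as spurious bone: an expansion of the skull into tissue
that is really brain. This module provides the quantitative side of the
QA programme around such artefacts:

* thickness estimation — the Hausdorff distance between a paired SFD
  delineation on CT and its sCT counterpart, read as the largest artefact
  thickness expected;
* margin recommendation — the mean thickness over a set of artefacts,
  rounded up to the nearest 0.5 mm, used as the brain-adjustment margin;
* the boolean coverage pipeline — with the adjusted planning target volume
  (PTV_a) as control region, intersection volumes of sCT bone and of each
  per-fraction cone-beam-CT (CBCT) bone are extracted, their difference is
  the artefact volume V_A for that fraction, and the part of V_A left
  outside an evaluated PTV is the uncovered volume;
* detection and classification of artefact components (types 1a/1b/1c by
  position relative to the skull) and of bone gaps (type 3, partial or
  full-thickness) with a 3 cm QA tolerance on gap length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import UndefinedMetricError, ValidationError
from .grids import BinaryStructure, intersect, subtract
from .metrics import compute_hd

Pathway = Literal["adjusted", "non_adjusted"]
ArtefactType = Literal["1a", "1b", "1c", "3_partial", "3_total"]

_FACE = ndimage.generate_binary_structure(3, 1)
_FULL = ndimage.generate_binary_structure(3, 3)

#: Components of a bone difference below this volume are treated as
#: resampling/segmentation speckle, not artefacts.
DEFAULT_COMPONENT_FLOOR_CC = 0.01

#: QA tolerance on bone-gap length: longer gaps require review.
GAP_TOLERANCE_MM = 30.0


@dataclass(frozen=True)
class CoverageResult:
    """Eq-style coverage volumes for one CBCT fraction.

    ``iv_sct_cc``/``iv_cbct_cc`` are the intersections of the sCT and
    per-fraction CBCT bone with the control PTV; ``v_a_cc`` is the artefact
    volume (their set difference) and ``v_uncov_cc`` the part of it outside
    the evaluated PTV.
    """

    fraction_index: int
    pathway: Pathway
    iv_sct_cc: float
    iv_cbct_cc: float
    v_a_cc: float
    v_uncov_cc: float
    uncovered_fraction_pct: float


@dataclass
class ArtefactRecord:
    """One detected artefact component or bone gap."""

    component_id: int
    artefact_type: ArtefactType | Literal["unclassified"]
    volume_cc: float
    thickness_mm: float | None = None
    length_mm: float | None = None
    qa_flag: Literal["pass", "review"] = "pass"
    structure: BinaryStructure | None = field(default=None, repr=False)


def estimate_sfd_thickness(
    sfd_ct: BinaryStructure, sfd_sct: BinaryStructure
) -> float:
    """Largest expected artefact thickness from a paired SFD delineation.

    The CT-side structure covers the device itself; the sCT-side structure
    additionally contains the artefact protrusion. All edges other than
    the one extruding into the brain coincide, so the Hausdorff distance
    between the two is the protrusion's depth.
    """
    if sfd_ct.is_empty or sfd_sct.is_empty:
        raise UndefinedMetricError("SFD thickness requires two non-empty masks")
    sfd_ct.grid.require_compatible(sfd_sct.grid)
    if (sfd_ct.mask & ~sfd_sct.mask).any():
        warnings.warn(
            "CT-side SFD structure is not contained in the sCT-side structure; "
            "the Hausdorff distance may not represent artefact thickness",
            stacklevel=2,
        )
    return compute_hd(sfd_ct, sfd_sct)


def margin_recommendation(thicknesses_mm: list[float]) -> float:
    """Mean thickness rounded up to the nearest 0.5 mm."""
    if len(thicknesses_mm) == 0:
        raise ValidationError("at least one thickness is required")
    if any(t < 0 for t in thicknesses_mm):
        raise ValidationError("thicknesses must be non-negative")
    mean = float(np.mean(thicknesses_mm))
    return float(np.ceil(mean / 0.5 - 1e-9) * 0.5)


def coverage_analysis(
    b_sct: BinaryStructure,
    b_cbct: BinaryStructure,
    ptv_control: BinaryStructure,
    ptv_eval: BinaryStructure,
    pathway: Pathway,
    fraction_index: int = 1,
    return_masks: bool = False,
):
    """Boolean artefact-coverage pipeline for one CBCT fraction.

    With the adjusted PTV as control region in both pathways::

        IV_CBCT = B_CBCT ^ PTV_control
        IV_sCT  = B_sCT  ^ PTV_control
        V_A     = IV_sCT  \\  IV_CBCT
        V_uncov = V_A     \\  PTV_eval

    All structures must already share one grid (the CBCT bone resampled
    upstream). The artefact volume is computed once against the control
    PTV and reused when the evaluated PTV is the non-adjusted one, so both
    pathways score the same artefact. ``uncovered_fraction_pct`` is
    ``100 * V_uncov / V_A`` (zero when there is no artefact volume).
    """
    for other in (b_cbct, ptv_control, ptv_eval):
        b_sct.grid.require_compatible(other.grid)
    if ptv_control.is_empty:
        raise ValidationError("control PTV is empty")

    iv_cbct = intersect(b_cbct, ptv_control)
    iv_sct = intersect(b_sct, ptv_control)
    v_a = subtract(iv_sct, iv_cbct)
    v_uncov = subtract(v_a, ptv_eval)

    v_a_cc = v_a.volume_cc
    v_uncov_cc = v_uncov.volume_cc
    result = CoverageResult(
        fraction_index=fraction_index,
        pathway=pathway,
        iv_sct_cc=iv_sct.volume_cc,
        iv_cbct_cc=iv_cbct.volume_cc,
        v_a_cc=v_a_cc,
        v_uncov_cc=v_uncov_cc,
        uncovered_fraction_pct=100.0 * v_uncov_cc / v_a_cc if v_a_cc > 0 else 0.0,
    )
    if return_masks:
        masks = {"iv_cbct": iv_cbct, "iv_sct": iv_sct, "v_a": v_a, "v_uncov": v_uncov}
        return result, masks
    return result


def _components(
    diff: BinaryStructure, min_volume_cc: float
) -> list[tuple[int, BinaryStructure]]:
    labels, n = ndimage.label(diff.mask, structure=_FULL)
    out = []
    voxel_cc = diff.grid.voxel_volume_mm3 / 1000.0
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    cid = 0
    for lab in range(1, n + 1):
        if counts[lab] * voxel_cc < min_volume_cc:
            continue
        cid += 1
        out.append((cid, diff.with_mask(labels == lab, name=f"component_{cid}")))
    return out


def detect_sfd_components(
    bone_sct: BinaryStructure,
    bone_ref: BinaryStructure,
    min_volume_cc: float = DEFAULT_COMPONENT_FLOOR_CC,
) -> list[ArtefactRecord]:
    """Candidate SFD artefacts: where sCT bone exceeds the reference bone.

    Connected components (26-connectivity) of ``bone_sct \\ bone_ref``
    above the volume floor become candidate artefacts, initially
    unclassified.
    """
    diff = subtract(bone_sct, bone_ref)
    records = []
    for cid, comp in _components(diff, min_volume_cc):
        records.append(
            ArtefactRecord(
                component_id=cid,
                artefact_type="unclassified",
                volume_cc=comp.volume_cc,
                structure=comp,
            )
        )
    return records


def _touches(component: np.ndarray, region: np.ndarray) -> bool:
    """True iff some component voxel is 6-adjacent to (or inside) the region."""
    grown = ndimage.binary_dilation(component, structure=_FACE)
    return bool((grown & region).any())


def classify_sfd_type(
    component: BinaryStructure,
    bone_ref: BinaryStructure,
    brain: BinaryStructure,
) -> Literal["1a", "1b", "1c"]:
    """Position-based sub-classification of one SFD artefact component.

    * ``1c`` — detached: no face adjacency to the reference bone;
    * ``1a`` — through-going: the component reaches both sides of the
      skull, touching the brain on the inside and non-brain soft
      tissue/air (scalp side) on the outside;
    * ``1b`` — attached to bone but visible on the inner (brain) side
      only.

    The side regions are derived from the reference bone and brain masks:
    the inner side is the brain itself, the outer side is everything that
    is neither reference bone, brain nor the component.
    """
    if component.is_empty:
        raise ValidationError("cannot classify an empty component")
    component.grid.require_compatible(bone_ref.grid)
    component.grid.require_compatible(brain.grid)

    if not _touches(component.mask, bone_ref.mask):
        return "1c"

    exterior = ~bone_ref.mask & ~brain.mask & ~component.mask
    if _touches(component.mask, brain.mask) and _touches(component.mask, exterior):
        return "1a"
    return "1b"


def _max_chord_mm(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Largest pairwise distance between voxel centers of a component."""
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) <= 1500:
        return float(pdist(pts).max())
    try:
        hull = ConvexHull(pts, qhull_options="QJ")
        pts = pts[hull.vertices]
    except QhullError:
        # Degenerate (e.g. collinear) point set: fall back to extremes
        # along the coordinate axes and the main diagonals.
        dirs = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1], [1, -1, 0], [1, 0, -1], [0, 1, -1], [1, 1, -1]],
            dtype=float,
        )
        proj = pts @ dirs.T
        keep = np.unique(np.concatenate([proj.argmin(axis=0), proj.argmax(axis=0)]))
        pts = pts[keep]
    return float(pdist(pts).max())


def detect_bone_gaps(
    bone_sct: BinaryStructure,
    bone_ref: BinaryStructure,
    brain: BinaryStructure | None = None,
    min_volume_cc: float = DEFAULT_COMPONENT_FLOOR_CC,
    tolerance_mm: float = GAP_TOLERANCE_MM,
) -> list[ArtefactRecord]:
    """Bone gaps (type 3): where reference bone is missing from sCT bone.

    Per connected component the length is the maximal chord between voxel
    centers. A gap is *total* when it spans the full local bone thickness
    — its voxels are adjacent both to the brain side and to the exterior
    side of the skull — else *partial*. Gaps longer than the QA tolerance
    (3 cm) are flagged for review.

    When a brain mask is given, the brain side is taken from it; otherwise
    the interior is inferred from the cavity components of the reference
    bone's complement.
    """
    diff = subtract(bone_ref, bone_sct)
    records: list[ArtefactRecord] = []
    comps = _components(diff, min_volume_cc)
    if not comps:
        return records

    if brain is not None:
        brain.grid.require_compatible(bone_ref.grid)
        inner_region = brain.mask
        exterior_region = ~bone_ref.mask & ~brain.mask & ~diff.mask
    else:
        labels, n = ndimage.label(~bone_ref.mask, structure=_FACE)
        border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
        border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
        border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
        border_labels.discard(0)
        exterior_region = np.isin(labels, sorted(border_labels)) & ~bone_ref.mask
        inner_region = ~bone_ref.mask & ~exterior_region

    for cid, comp in comps:
        length = _max_chord_mm(comp.mask, comp.grid.spacing)
        total = _touches(comp.mask, inner_region) and _touches(comp.mask, exterior_region)
        records.append(
            ArtefactRecord(
                component_id=cid,
                artefact_type="3_total" if total else "3_partial",
                volume_cc=comp.volume_cc,
                length_mm=length,
                qa_flag="review" if length > tolerance_mm else "pass",
                structure=comp,
            )
        )
    return records
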