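"""Congruence metrics between paired structures.

Structure-set agreement is quantified with four metrics: the Dice
similarity coefficient (DSC, volumetric overlap), the Hausdorff distance
(HD, worst-case surface separation), the average Hausdorff distance (AHD,
typical surface separation) and the structure volume. A pair is banded as
*high* congruence when DSC > 0.7 together with AHD <= 1 mm, *low* when
DSC < 0.7 together with AHD > 1 mm, and *indeterminate* otherwise; the 0.7
cut acknowledges that DSC penalises small-volume structures.

Surface distances are computed between the centers of *surface voxels*:
mask voxels with at least one 6-neighbour outside the mask (voxels on the
array border count as surface). HD is the true maximum, not a percentile,
because downstream artefact-thickness analysis reads it as the largest
protrusion expected. AHD combines the two directed mean nearest-neighbour
distances by their maximum by default; the arithmetic-mean combination is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .grids import BinaryStructure, resample_to_grid

Band = Literal["high", "low", "indeterminate"]

_FACE_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class CongruenceResult:
    """Metrics for one reference-test structure pair."""

    name: str
    dsc: float
    hd_mm: float
    ahd_mm: float
    volume_ref_cc: float
    volume_test_cc: float
    band: Band


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask."""
    return mask & ~ndimage.binary_erosion(mask, structure=_FACE_CONN, border_value=0)


def surface_points_mm(s: BinaryStructure) -> np.ndarray:
    """World-offset coordinates (mm) of surface voxel centers, shape (n, 3)."""
    pts = np.argwhere(surface_mask(s.mask)).astype(float)
    return pts * np.asarray(s.grid.spacing)


def compute_dsc(a: BinaryStructure, b: BinaryStructure) -> float:
    """Dice similarity coefficient ``2|A ^ B| / (|A| + |B|)``."""
    a.grid.require_compatible(b.grid)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        raise UndefinedMetricError("DSC is undefined for two empty masks")
    overlap = int((a.mask & b.mask).sum())
    return 2.0 * overlap / (na + nb)


def _directed_distances(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance from each point of A to the set B."""
    tree = cKDTree(points_b)
    d, _ = tree.query(points_a, k=1)
    return d


def _surface_distance_pair(
    a: BinaryStructure, b: BinaryStructure
) -> tuple[np.ndarray, np.ndarray]:
    a.grid.require_compatible(b.grid)
    if a.is_empty or b.is_empty:
        raise UndefinedMetricError(
            "surface distances are undefined when a mask is empty "
            f"({a.name!r}: {a.voxel_count} voxels, {b.name!r}: {b.voxel_count} voxels)"
        )
    pa, pb = surface_points_mm(a), surface_points_mm(b)
    return _directed_distances(pa, pb), _directed_distances(pb, pa)


def compute_hd(a: BinaryStructure, b: BinaryStructure) -> float:
    """Symmetric Hausdorff distance (mm): max of the two directed maxima."""
    d_ab, d_ba = _surface_distance_pair(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def compute_ahd(
    a: BinaryStructure, b: BinaryStructure, combine: Literal["max", "mean"] = "max"
) -> float:
    """Average Hausdorff distance (mm).

    The two directed mean nearest-neighbour surface distances are combined
    by their maximum (default) or their arithmetic mean.
    """
    d_ab, d_ba = _surface_distance_pair(a, b)
    means = (float(d_ab.mean()), float(d_ba.mean()))
    if combine == "max":
        return max(means)
    if combine == "mean":
        return 0.5 * (means[0] + means[1])
    raise ValidationError(f"unknown AHD combination {combine!r}")


def volume_cc(s: BinaryStructure) -> float:
    """Structure volume in cc (voxel count x spacing product / 1000)."""
    return s.volume_cc


def classify_congruence(dsc: float, ahd_mm: float) -> Band:
    """Band a pair by the DSC-0.7 / AHD-1 mm congruence rule."""
    if not 0.0 <= dsc <= 1.0:
        raise ValidationError(f"DSC must lie in [0, 1], got {dsc}")
    if ahd_mm < 0:
        raise ValidationError(f"AHD must be non-negative, got {ahd_mm}")
    if dsc > 0.7 and ahd_mm <= 1.0:
        return "high"
    if dsc < 0.7 and ahd_mm > 1.0:
        return "low"
    return "indeterminate"


def compare_structures(
    reference: BinaryStructure,
    test: BinaryStructure,
    ahd_combine: Literal["max", "mean"] = "max",
) -> CongruenceResult:
    """Full congruence evaluation of a reference-test pair.

    If the two structures live on different grids within one frame of
    reference, the test structure is resampled onto the *reference* grid
    first, so results are reproducible regardless of acquisition grids.
    """
    if not reference.grid.compatible(test.grid):
        test = resample_to_grid(test, reference.grid)
    dsc = compute_dsc(reference, test)
    hd = compute_hd(reference, test)
    ahd = compute_ahd(reference, test, combine=ahd_combine)
    return CongruenceResult(
        name=reference.name,
        dsc=dsc,
        hd_mm=hd,
        ahd_mm=ahd,
        volume_ref_cc=reference.volume_cc,
        volume_test_cc=test.volume_cc,
        band=classify_congruence(dsc, ahd),
    )
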