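"""Seeded synthetic head phantoms with paired CT / sCT / CBCT volumes.

The generator emulates the geometry that the artefact-analysis pipeline
assumes in real data: an ellipsoidal head of soft tissue containing an
ellipsoidal-shell skull and an interior brain, a spherical clinical target
volume (CTV) abutting the inner skull surface, and the synthetic-CT
rendering defects of surgical fixation devices (SFDs):

* type 1a — the device's signal void becomes a bone-valued cylinder
  through the skull, protruding a known thickness into the brain and
  capping slightly outward; the device's burr hole is absent from the
  true (CT) bone, so the rendered artefact spans the full shell;
* type 1b — an oblique device adds bone on the inner skull surface only;
* type 1c — a detached bone-valued island inside the brain;
* type 3 — bone gaps: rectangular patches of skull missing from the sCT,
  of known chord length, either partial (outer half) or full thickness.

CT, sCT and CBCT volumes live on their own grids (defaults 1.00/1.00/2.00,
0.68/0.68/1.00 and 1.00/1.00/1.00 mm) sharing one frame of reference; the
CBCT geometry is rigidly shifted per fraction to emulate set-up error.
Gaussian HU noise is added per modality and never alters the ground-truth
masks. Identical spec and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np

from .errors import ValidationError
from .grids import BinaryStructure, HUVolume, ImageGrid

HU_AIR = -1000.0
HU_SOFT = 40.0
HU_BONE = 1000.0

#: Outward cap height of a type-1a artefact beyond the outer skull surface.
_CAP_OUT_MM = 1.5
#: How far a type-1b protrusion overlaps into the shell so it stays attached.
_ATTACH_MM = 1.5
#: Tangential width of a bone-gap patch.
_GAP_WIDTH_MM = 6.0


@dataclass(frozen=True)
class ArtefactSpec:
    """One SFD artefact to render into the sCT bone."""

    artefact_type: Literal["1a", "1b", "1c"]
    thickness_mm: float = 3.0
    radius_mm: float = 5.0
    detach_mm: float = 3.0  # 1c only: gap between island and inner bone
    direction: tuple[float, float, float] | None = None  # None: placed near CTV


@dataclass(frozen=True)
class GapSpec:
    """One bone gap (type 3 artefact) to carve out of the sCT skull."""

    length_mm: float = 20.0
    full_thickness: bool = True
    direction: tuple[float, float, float] | None = None  # None: opposite the CTV


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; defaults mirror the study's imaging set-up."""

    spacing_ct: tuple[float, float, float] = (1.0, 1.0, 2.0)
    spacing_sct: tuple[float, float, float] = (0.68, 0.68, 1.0)
    spacing_cbct: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_radii_mm: tuple[float, float, float] = (65.0, 80.0, 60.0)
    scalp_thickness_mm: float = 6.0
    skull_thickness_mm: float = 6.0
    artefacts: tuple[ArtefactSpec, ...] = (ArtefactSpec("1a"),)
    bone_gaps: tuple[GapSpec, ...] = ()
    ctv_radius_mm: float = 20.0
    ctv_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    ctv_gap_mm: float = 0.0
    ptv_margin_mm: float = 3.0
    cbct_shifts_mm: tuple[tuple[float, float, float], ...] = ((0.5, -0.5, 0.5),)
    noise_sigma_hu: float = 20.0
    pad_mm: float = 8.0
    frame_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        shell = self.scalp_thickness_mm + self.skull_thickness_mm
        if shell >= min(self.head_radii_mm):
            raise ValidationError(
                f"scalp+skull thickness {shell} mm must be smaller than the "
                f"smallest head radius {min(self.head_radii_mm)} mm"
            )
        if self.ctv_radius_mm <= 0:
            raise ValidationError("CTV radius must be positive")
        for a in self.artefacts:
            if a.thickness_mm <= 0 or a.radius_mm <= 0:
                raise ValidationError("artefact thickness and radius must be positive")
        for g in self.bone_gaps:
            if g.length_mm <= 0:
                raise ValidationError("gap length must be positive")
        if not self.cbct_shifts_mm:
            raise ValidationError("at least one CBCT fraction shift is required")
        # CTV must fit inside the brain along its placement direction.
        inner = self.inner_skull_radii_mm
        u = _unit(self.ctv_direction)
        reach = 1.0 / np.sqrt(sum((u[j] / inner[j]) ** 2 for j in range(3)))
        if self.ctv_gap_mm + 2 * self.ctv_radius_mm > reach:
            raise ValidationError("CTV does not fit inside the brain")

    @property
    def outer_skull_radii_mm(self) -> tuple[float, float, float]:
        return tuple(r - self.scalp_thickness_mm for r in self.head_radii_mm)

    @property
    def inner_skull_radii_mm(self) -> tuple[float, float, float]:
        return tuple(r - self.scalp_thickness_mm - self.skull_thickness_mm
                     for r in self.head_radii_mm)

    @property
    def n_fractions(self) -> int:
        return len(self.cbct_shifts_mm)

    def grid(self, modality: Literal["CT", "sCT", "CBCT"]) -> ImageGrid:
        spacing = {
            "CT": self.spacing_ct, "sCT": self.spacing_sct, "CBCT": self.spacing_cbct
        }[modality]
        shape = tuple(
            int(np.ceil(2 * (r + self.pad_mm) / sp))
            for r, sp in zip(self.head_radii_mm, spacing)
        )
        origin = tuple(-(n - 1) * sp / 2.0 for n, sp in zip(shape, spacing))
        return ImageGrid(spacing=spacing, origin=origin, shape=shape,
                         frame_id=self.frame_id)


@dataclass
class ArtefactTruth:
    artefact_type: Literal["1a", "1b", "1c"]
    thickness_mm: float | None
    mask: BinaryStructure  # sCT grid; the spurious-bone voxels
    sfd_ct: BinaryStructure | None  # paired device delineations (1a/1b)
    sfd_sct: BinaryStructure | None


@dataclass
class GapTruth:
    length_mm: float
    full_thickness: bool
    mask: BinaryStructure  # sCT grid; the missing-bone voxels


@dataclass
class PhantomTruth:
    """Ground-truth structures on each modality grid."""

    body_ct: BinaryStructure
    bone_ct: BinaryStructure
    brain_ct: BinaryStructure
    ctv_ct: BinaryStructure
    body_sct: BinaryStructure
    bone_sct: BinaryStructure
    bone_ref_sct: BinaryStructure  # true bone geometry on the sCT grid
    brain_sct: BinaryStructure
    ctv_sct: BinaryStructure
    bone_cbct: list[BinaryStructure]  # one per fraction, on the CBCT grid
    artefacts: list[ArtefactTruth]
    gaps: list[GapTruth]


@dataclass
class Phantom:
    spec: PhantomSpec
    ct: HUVolume
    sct: HUVolume
    cbct: HUVolume  # first fraction
    truth: PhantomTruth


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("direction vector must be non-zero")
    return v / n


def _rotate_about_z(u: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1], u[2]])


def _surface_point(direction: np.ndarray, radii) -> np.ndarray:
    """Point on the ellipsoid with the given half-axes along a direction."""
    t = 1.0 / np.sqrt(sum((direction[j] / radii[j]) ** 2 for j in range(3)))
    return t * direction


def _normal_at(p: np.ndarray, radii) -> np.ndarray:
    return _unit(np.array([p[j] / radii[j] ** 2 for j in range(3)]))


def _depth_to_inner(p: np.ndarray, n: np.ndarray, inner_radii) -> float:
    """Distance from p along -n to the first crossing of the inner ellipsoid."""
    a = sum((n[j] / inner_radii[j]) ** 2 for j in range(3))
    b = -2.0 * sum(p[j] * n[j] / inner_radii[j] ** 2 for j in range(3))
    c = sum((p[j] / inner_radii[j]) ** 2 for j in range(3)) - 1.0
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise ValidationError("artefact axis does not reach the inner skull surface")
    return float((-b - np.sqrt(disc)) / (2 * a))


@dataclass(frozen=True)
class _Cylinder:
    """Geometry of one artefact site, precomputed in world coordinates."""

    spec: ArtefactSpec
    anchor: np.ndarray  # point on outer skull surface
    normal: np.ndarray  # outward unit normal at the anchor
    depth: float        # local shell thickness along the axis


def _artefact_sites(spec: PhantomSpec) -> list[_Cylinder]:
    base = _unit(spec.ctv_direction)
    # Fan artefacts out around the target so multiple sites stay disjoint.
    offsets = [0.0]
    for k in range(1, len(spec.artefacts)):
        sign = 1 if k % 2 else -1
        offsets.append(sign * np.deg2rad(35.0 * ((k + 1) // 2)))
    sites = []
    for art, off in zip(spec.artefacts, offsets):
        u = _unit(art.direction) if art.direction is not None else _rotate_about_z(base, off)
        p = _surface_point(u, spec.outer_skull_radii_mm)
        n = _normal_at(p, spec.outer_skull_radii_mm)
        d = _depth_to_inner(p, n, spec.inner_skull_radii_mm)
        sites.append(_Cylinder(spec=art, anchor=p, normal=n, depth=d))
    return sites


def _gap_sites(spec: PhantomSpec) -> list[tuple[GapSpec, np.ndarray]]:
    base = _unit(spec.ctv_direction)
    out = []
    for k, gap in enumerate(spec.bone_gaps):
        if gap.direction is not None:
            u = _unit(gap.direction)
        else:
            # Opposite hemisphere from the target, fanned widely so even
            # long gaps stay disjoint.
            sign = 1 if k % 2 else -1
            u = _rotate_about_z(base, np.deg2rad(180.0 + sign * 75.0 * ((k + 1) // 2)))
        out.append((gap, u))
    return out


class _Field:
    """Broadcastable world-coordinate axes of a grid, optionally shifted."""

    def __init__(self, grid: ImageGrid, shift=(0.0, 0.0, 0.0)):
        self.x = (grid.axis_coords(0) - shift[0]).astype(np.float32)[:, None, None]
        self.y = (grid.axis_coords(1) - shift[1]).astype(np.float32)[None, :, None]
        self.z = (grid.axis_coords(2) - shift[2]).astype(np.float32)[None, None, :]

    def ellipsoid(self, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
        return (
            ((self.x - center[0]) / radii[0]) ** 2
            + ((self.y - center[1]) / radii[1]) ** 2
            + ((self.z - center[2]) / radii[2]) ** 2
        ) <= 1.0

    def sphere(self, center, radius) -> np.ndarray:
        return (
            (self.x - center[0]) ** 2
            + (self.y - center[1]) ** 2
            + (self.z - center[2]) ** 2
        ) <= radius**2

    def cylinder_coords(self, site: _Cylinder) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate s (positive outward) and squared radial
        distance about the artefact axis, for every voxel."""
        dx = self.x - site.anchor[0]
        dy = self.y - site.anchor[1]
        dz = self.z - site.anchor[2]
        s = dx * site.normal[0] + dy * site.normal[1] + dz * site.normal[2]
        rho2 = dx**2 + dy**2 + dz**2 - s**2
        return s, rho2

    def slab(self, point, e_vec, half_extent) -> np.ndarray:
        t = (
            (self.x - point[0]) * e_vec[0]
            + (self.y - point[1]) * e_vec[1]
            + (self.z - point[2]) * e_vec[2]
        )
        return np.abs(t) <= half_extent

    def hemisphere(self, direction) -> np.ndarray:
        return (self.x * direction[0] + self.y * direction[1]
                + self.z * direction[2]) >= 0


def _ctv_center(spec: PhantomSpec) -> np.ndarray:
    u = _unit(spec.ctv_direction)
    reach = 1.0 / np.sqrt(sum((u[j] / spec.inner_skull_radii_mm[j]) ** 2 for j in range(3)))
    return u * (reach - spec.ctv_gap_mm - spec.ctv_radius_mm)


def _gap_region(f: _Field, spec: PhantomSpec, gap: GapSpec, u: np.ndarray) -> np.ndarray:
    """Rectangular skull patch whose maximal chord is the requested length."""
    mid_radii = tuple(r - spec.skull_thickness_mm / 2 for r in spec.outer_skull_radii_mm)
    p = _surface_point(u, mid_radii)
    n = _normal_at(p, mid_radii)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(n, helper)) > 0.95:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    th = spec.skull_thickness_mm if gap.full_thickness else spec.skull_thickness_mm / 2
    chord2 = gap.length_mm**2 - _GAP_WIDTH_MM**2 - th**2
    half_e1 = np.sqrt(max(chord2, _GAP_WIDTH_MM**2)) / 2
    region = (
        f.slab(p, e1, half_e1)
        & f.slab(p, e2, _GAP_WIDTH_MM / 2)
        & f.hemisphere(u)
    )
    if not gap.full_thickness:
        region &= ~f.ellipsoid(mid_radii)  # outer half of the shell only
    return region


def _build_geometry(
    grid: ImageGrid,
    spec: PhantomSpec,
    shift=(0.0, 0.0, 0.0),
    with_sct_defects: bool = False,
    with_details: bool = False,
) -> dict:
    """Evaluate all membership predicates of the phantom on one grid.

    ``shift`` translates the whole anatomy rigidly (used for CBCT set-up
    error). With ``with_sct_defects`` the bone mask carries artefacts and
    gaps; ``with_details`` additionally returns per-artefact and per-gap
    masks plus the paired SFD delineations.
    """
    f = _Field(grid, shift)
    body = f.ellipsoid(spec.head_radii_mm)
    outer = f.ellipsoid(spec.outer_skull_radii_mm)
    inner = f.ellipsoid(spec.inner_skull_radii_mm)
    skull = outer & ~inner

    sites = _artefact_sites(spec)
    holes = np.zeros_like(skull)
    cyl_coords = []
    for site in sites:
        s, rho2 = f.cylinder_coords(site)
        cyl_coords.append((s, rho2))
        if site.spec.artefact_type == "1a":
            r_hole = min(2.0, 0.4 * site.spec.radius_mm)
            holes |= (
                (rho2 <= r_hole**2)
                & (s >= -(site.depth + 0.5))
                & (s <= 0.5)
                & skull
            )
    bone_true = skull & ~holes

    out = {
        "body": body,
        "interior": inner,
        "bone_true": bone_true,
        "brain": inner & ~bone_true,
        "ctv": f.sphere(_ctv_center(spec), spec.ctv_radius_mm),
    }
    if not with_sct_defects:
        out["bone"] = bone_true
        return out

    adds = np.zeros_like(skull)
    artefact_masks = []
    sfd_pairs = []
    for site, (s, rho2) in zip(sites, cyl_coords):
        art = site.spec
        t, r, d = art.thickness_mm, art.radius_mm, site.depth
        in_radius = rho2 <= r**2
        if art.artefact_type == "1a":
            add = in_radius & (s >= -(d + t)) & (s <= _CAP_OUT_MM)
        elif art.artefact_type == "1b":
            add = in_radius & (s >= -(d + t)) & (s <= -(d - _ATTACH_MM))
        else:  # 1c: detached island
            r_is = 0.6 * r
            center = site.anchor - site.normal * (d + art.detach_mm + r_is + t / 2)
            add = f.sphere(center, r_is)
        adds |= add
        artefact_masks.append(add & ~bone_true)
        if art.artefact_type in ("1a", "1b"):
            sfd_ct = in_radius & (s >= -d) & (s <= -d / 2)
            sfd_sct = in_radius & (s >= -(d + t)) & (s <= -d / 2)
            sfd_pairs.append((sfd_ct, sfd_sct))
        else:
            sfd_pairs.append(None)

    gap_masks = []
    gaps_all = np.zeros_like(skull)
    for gap, u in _gap_sites(spec):
        region = _gap_region(f, spec, gap, u)
        gap_masks.append(region & bone_true)
        gaps_all |= region

    bone_sct = (bone_true | adds) & ~gaps_all
    out["bone"] = bone_sct
    out["brain"] = inner & ~bone_sct
    if with_details:
        out["artefact_masks"] = artefact_masks
        out["sfd_pairs"] = sfd_pairs
        out["gap_masks"] = gap_masks
    return out


def _mk(name, modality, grid, mask) -> BinaryStructure:
    return BinaryStructure(name=name, modality=modality, grid=grid, mask=mask)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate paired CT/sCT/CBCT volumes and their ground truth."""
    rng = np.random.default_rng(spec.seed)
    grid_ct, grid_sct, grid_cbct = (spec.grid(m) for m in ("CT", "sCT", "CBCT"))

    geo_ct = _build_geometry(grid_ct, spec)
    geo_sct = _build_geometry(grid_sct, spec, with_sct_defects=True, with_details=True)
    geo_ref_sct = _build_geometry(grid_sct, spec)

    def hu_volume(grid, geo, modality) -> HUVolume:
        vals = np.full(grid.shape, HU_AIR, dtype=np.float32)
        vals[geo["body"]] = HU_SOFT
        vals[geo["bone"]] = HU_BONE
        if spec.noise_sigma_hu > 0:
            vals += rng.normal(0.0, spec.noise_sigma_hu, grid.shape).astype(np.float32)
        return HUVolume(grid=grid, values=vals, modality=modality)

    ct = hu_volume(grid_ct, geo_ct, "CT")
    sct = hu_volume(grid_sct, geo_sct, "sCT")

    geo_cbct_first = _build_geometry(grid_cbct, spec, shift=spec.cbct_shifts_mm[0])
    cbct = hu_volume(grid_cbct, geo_cbct_first, "CBCT")
    bone_cbct = [_mk("bone", "CBCT", grid_cbct, geo_cbct_first["bone"])]
    for shift in spec.cbct_shifts_mm[1:]:
        geo_i = _build_geometry(grid_cbct, spec, shift=shift)
        bone_cbct.append(_mk("bone", "CBCT", grid_cbct, geo_i["bone"]))

    artefacts = []
    for art, mask, pair in zip(
        spec.artefacts, geo_sct["artefact_masks"], geo_sct["sfd_pairs"]
    ):
        artefacts.append(
            ArtefactTruth(
                artefact_type=art.artefact_type,
                thickness_mm=art.thickness_mm if art.artefact_type != "1c" else None,
                mask=_mk("artefact", "sCT", grid_sct, mask),
                sfd_ct=_mk("SFD", "CT", grid_sct, pair[0]) if pair else None,
                sfd_sct=_mk("SFD", "sCT", grid_sct, pair[1]) if pair else None,
            )
        )
    gaps = [
        GapTruth(length_mm=g.length_mm, full_thickness=g.full_thickness,
                 mask=_mk("gap", "sCT", grid_sct, m))
        for g, m in zip(spec.bone_gaps, geo_sct["gap_masks"])
    ]

    truth = PhantomTruth(
        body_ct=_mk("body", "CT", grid_ct, geo_ct["body"]),
        bone_ct=_mk("bone", "CT", grid_ct, geo_ct["bone"]),
        brain_ct=_mk("brain", "CT", grid_ct, geo_ct["brain"]),
        ctv_ct=_mk("CTV", "CT", grid_ct, geo_ct["ctv"]),
        body_sct=_mk("body", "sCT", grid_sct, geo_sct["body"]),
        bone_sct=_mk("bone", "sCT", grid_sct, geo_sct["bone"]),
        bone_ref_sct=_mk("bone", "derived", grid_sct, geo_ref_sct["bone"]),
        brain_sct=_mk("brain", "sCT", grid_sct, geo_sct["brain"]),
        ctv_sct=_mk("CTV", "sCT", grid_sct, geo_sct["ctv"]),
        bone_cbct=bone_cbct,
        artefacts=artefacts,
        gaps=gaps,
    )
    return Phantom(spec=spec, ct=ct, sct=sct, cbct=cbct, truth=truth)


@dataclass(frozen=True)
class CohortDistribution:
    """Per-phantom parameter ranges for cohort generation.

    Artefact thickness is drawn uniformly from ``thickness_range``
    (default 2.0-4.5 mm, the band observed clinically for clamp-type SFD
    artefacts); each fraction's set-up shift is drawn uniformly per axis
    from ``+- shift_range_mm``.
    """

    thickness_range: tuple[float, float] = (2.0, 4.5)
    artefact_types: tuple[str, ...] = ("1a",)
    radius_mm: float = 5.0
    n_fractions: int = 5
    shift_range_mm: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.thickness_range
        if not 0 < lo <= hi:
            raise ValidationError(f"invalid thickness range {self.thickness_range}")
        if self.n_fractions < 1:
            raise ValidationError("at least one fraction is required")


def draw_cohort_specs(
    n: int,
    distribution: CohortDistribution = CohortDistribution(),
    seed: int = 0,
    base_spec: PhantomSpec = PhantomSpec(),
) -> list[PhantomSpec]:
    """Draw ``n`` phantom specifications, reproducibly from the seed."""
    if n < 1:
        raise ValidationError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        t = float(rng.uniform(*distribution.thickness_range))
        a_type = distribution.artefact_types[i % len(distribution.artefact_types)]
        shifts = tuple(
            tuple(float(v) for v in rng.uniform(
                -distribution.shift_range_mm, distribution.shift_range_mm, 3))
            for _ in range(distribution.n_fractions)
        )
        specs.append(
            replace(
                base_spec,
                artefacts=(ArtefactSpec(a_type, thickness_mm=t,
                                        radius_mm=distribution.radius_mm),),
                cbct_shifts_mm=shifts,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_cohort(
    n: int,
    distribution: CohortDistribution = CohortDistribution(),
    seed: int = 0,
    base_spec: PhantomSpec = PhantomSpec(),
) -> Iterator[Phantom]:
    """Lazily generate a cohort of phantoms (memory stays per-phantom)."""
    for s in draw_cohort_specs(n, distribution, seed, base_spec):
        yield generate_phantom(s)
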