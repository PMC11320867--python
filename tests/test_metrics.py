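import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sctqa.errors import UndefinedMetricError, ValidationError
from sctqa.grids import BinaryStructure, ImageGrid
from sctqa.metrics import (
    classify_congruence,
    compare_structures,
    compute_ahd,
    compute_dsc,
    compute_hd,
    surface_mask,
    volume_cc,
)

from conftest import make_structure


def brute_force_surface_distances(a, b):
    """All-pairs oracle for HD and AHD over surface voxel centers."""
    sp = np.asarray(a.grid.spacing)
    pa = np.argwhere(surface_mask(a.mask)) * sp
    pb = np.argwhere(surface_mask(b.mask)) * sp
    d = cdist(pa, pb)
    d_ab, d_ba = d.min(axis=1), d.min(axis=0)
    return max(d_ab.max(), d_ba.max()), max(d_ab.mean(), d_ba.mean())


class TestDsc:
    def test_identical_and_disjoint(self, unit_grid):
        a = make_structure(unit_grid, [(0, 0, 0), (1, 1, 1)])
        b = make_structure(unit_grid, [(5, 5, 5)])
        assert compute_dsc(a, a) == 1.0
        assert compute_dsc(a, b) == 0.0

    def test_partial_overlap_counts(self, unit_grid):
        a = make_structure(unit_grid, [(0, 0, 0), (1, 0, 0)])
        b = make_structure(unit_grid, [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        assert compute_dsc(a, b) == pytest.approx(2 * 2 / 6)
        assert compute_dsc(b, a) == compute_dsc(a, b)

    def test_two_empty_masks_undefined(self, unit_grid):
        e = make_structure(unit_grid, [])
        with pytest.raises(UndefinedMetricError):
            compute_dsc(e, e)


class TestSurfaceDistances:
    def test_identical_masks_zero(self, unit_grid):
        a = make_structure(unit_grid, [(2, 2, 2), (3, 2, 2)])
        assert compute_hd(a, a) == 0.0
        assert compute_ahd(a, a) == 0.0

    def test_single_voxel_pairs(self, unit_grid):
        a = make_structure(unit_grid, [(0, 0, 0)])
        b = make_structure(unit_grid, [(3, 0, 0)])
        assert compute_hd(a, b) == pytest.approx(3.0)
        assert compute_ahd(a, b) == pytest.approx(3.0)

    def test_line_vs_center_voxel(self, unit_grid):
        line = make_structure(unit_grid, [(i, 0, 0) for i in range(5)])
        center = make_structure(unit_grid, [(2, 0, 0)])
        assert compute_hd(line, center) == pytest.approx(2.0)

    def test_directed_means_combined_by_max(self, unit_grid):
        a = make_structure(unit_grid, [(0, 0, 0)])
        b = make_structure(unit_grid, [(0, 0, 0), (2, 0, 0)])
        assert compute_ahd(a, b) == pytest.approx(1.0)
        assert compute_ahd(a, b, combine="mean") == pytest.approx(0.5)

    def test_empty_mask_raises(self, unit_grid):
        a = make_structure(unit_grid, [(0, 0, 0)])
        e = make_structure(unit_grid, [])
        for f in (compute_hd, compute_ahd):
            with pytest.raises(UndefinedMetricError):
                f(a, e)

    def test_translation_lower_bound(self, unit_grid):
        """Translating a voxel by k voxels makes HD at least k x spacing."""
        a = make_structure(unit_grid, [(1, 1, 1)])
        for k in (1, 2, 4):
            b = make_structure(unit_grid, [(1 + k, 1, 1)])
            assert compute_hd(a, b) >= k * 1.0

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 30:
            shape = tuple(rng.integers(3, 17, 3))
            spacing = tuple(rng.uniform(0.4, 2.5, 3))
            g = ImageGrid(spacing, (0, 0, 0), shape, "r")
            ma, mb = (rng.random(shape) < 0.15 for _ in range(2))
            if not (ma.any() and mb.any()):
                continue
            a = BinaryStructure("a", "CT", g, ma)
            b = BinaryStructure("b", "CT", g, mb)
            hd_o, ahd_o = brute_force_surface_distances(a, b)
            assert compute_hd(a, b) == pytest.approx(hd_o, abs=1e-9)
            assert compute_ahd(a, b) == pytest.approx(ahd_o, abs=1e-9)
            checked += 1


class TestVolume:
    def test_unit_cube_and_empty(self):
        g = ImageGrid((1, 1, 1), (0, 0, 0), (10, 10, 10), "v")
        full = BinaryStructure("a", "CT", g, np.ones(g.shape, bool))
        assert volume_cc(full) == pytest.approx(1.0)
        empty = BinaryStructure("e", "CT", g, np.zeros(g.shape, bool))
        assert volume_cc(empty) == 0.0

    def test_anisotropic_spacing(self):
        g = ImageGrid((0.68, 0.68, 1.0), (0, 0, 0), (10, 10, 10), "v")
        m = np.zeros(g.shape, bool)
        m.flat[:500] = True
        s = BinaryStructure("a", "sCT", g, m)
        assert volume_cc(s) == pytest.approx(500 * 0.68 * 0.68 * 1.0 / 1000)


class TestCongruenceBand:
    @pytest.mark.parametrize(
        "dsc,ahd,band",
        [
            (0.94, 0.04, "high"),   # target-level agreement
            (0.17, 1.37, "low"),    # small-gland-level disagreement
            (0.65, 0.5, "indeterminate"),
            (0.9, 1.5, "indeterminate"),
            (0.71, 1.0, "high"),
            (0.7, 0.5, "indeterminate"),  # boundary DSC is neither band
        ],
    )
    def test_rule_cases(self, dsc, ahd, band):
        assert classify_congruence(dsc, ahd) == band

    def test_out_of_range_dsc(self):
        with pytest.raises(ValidationError):
            classify_congruence(1.2, 0.5)


class TestCompareStructures:
    def test_cross_grid_comparison_on_reference_grid(self):
        # Same 14 mm cube drawn on a 1 mm and on a 0.7 mm grid: resampling
        # the test onto the reference grid must give near-perfect congruence.
        ref_g = ImageGrid((1, 1, 1), (0, 0, 0), (20, 20, 20), "f")
        test_g = ImageGrid((0.7, 0.7, 0.7), (0, 0, 0), (29, 29, 29), "f")

        def cube(g, lo=3.0, hi=17.0):
            c = [g.axis_coords(i) for i in range(3)]
            m = (
                (c[0][:, None, None] >= lo) & (c[0][:, None, None] <= hi)
                & (c[1][None, :, None] >= lo) & (c[1][None, :, None] <= hi)
                & (c[2][None, None, :] >= lo) & (c[2][None, None, :] <= hi)
            )
            return BinaryStructure("cube", "CT", g, m)

        res = compare_structures(cube(ref_g), cube(test_g))
        # Nearest-neighbour regridding leaves at most half a test voxel of
        # surface disagreement, so congruence stays high.
        assert res.band == "high"
        assert res.dsc > 0.85
        assert res.hd_mm <= 2.0
        assert res.ahd_mm <= 1.0
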