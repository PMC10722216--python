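import numpy as np
import pytest

from ttmorph import morphometry as mm
from ttmorph.simulate import SimTruth, generate_cell
from ttmorph.types import TubuleMask

from oracles import chord_angles_on_path


def _tm(mask):
    return TubuleMask(np.asarray(mask, dtype=bool), provenance="simulator_truth")


class TestAreaFraction:
    def test_full_mask_is_100(self):
        cm = np.ones((10, 10), dtype=bool)
        assert mm.area_fraction(_tm(cm), cm) == 100.0

    def test_simple_arithmetic(self):
        cm = np.ones((10, 10), dtype=bool)
        tub = np.zeros_like(cm)
        tub[:5, :5] = True
        assert mm.area_fraction(_tm(tub), cm) == 25.0

    def test_empty_cell_mask_errors(self):
        with pytest.raises(ValueError):
            mm.area_fraction(_tm(np.zeros((5, 5))), np.zeros((5, 5), dtype=bool))


class TestSkeletonize:
    def test_bar_skeleton_is_collinear_line(self):
        mask = np.zeros((20, 70), dtype=bool)
        mask[8:11, 10:60] = True  # 3 px wide, 50 long
        sk = mm.skeletonize(_tm(mask))
        assert abs(sk.length_px - 50) <= 2
        # collinear up to end-pixel artefacts of digital thinning
        rows, counts = np.unique(sk.pixels[:, 0], return_counts=True)
        assert counts.max() >= sk.length_px - 2

    def test_disk_collapses_to_central_cluster(self):
        from skimage.morphology import disk

        r = 9
        sk = mm.skeletonize(_tm(np.pad(disk(r), 2)))
        assert sk.length_px <= r
        center = np.array([r + 2, r + 2])
        assert np.all(np.linalg.norm(sk.pixels - center, axis=1) <= r)

    def test_plus_sign_has_one_degree4_branch_point(self):
        mask = np.zeros((31, 31), dtype=bool)
        mask[15, 5:26] = True
        mask[5:26, 15] = True
        sk = mm.skeletonize(_tm(mask))
        # brute-force neighbour count on the skeleton pixel set
        pixset = {tuple(p) for p in sk.pixels}
        degrees = [
            sum(
                (r + dr, c + dc) in pixset
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
            for r, c in sk.pixels
        ]
        # the centre pixel has degree 4; the branch-point cluster (its
        # 8-connected pixels of degree >= 3) is a single blob around it
        assert max(degrees) == 4
        hubs = sk.pixels[[i for i, d in enumerate(degrees) if d >= 3]]
        assert len(hubs) >= 1
        centre = np.array([15, 15])
        assert np.all(np.abs(hubs - centre).max(axis=1) <= 1)

    def test_empty_and_singleton(self):
        assert mm.skeletonize(_tm(np.zeros((5, 5)))).length_px == 0
        single = np.zeros((5, 5), dtype=bool)
        single[2, 2] = True
        sk = mm.skeletonize(_tm(single))
        assert sk.length_px == 1
        assert sk.orientations_deg[0] == 0.0


class TestLengthDensity:
    def test_empty_skeleton_is_zero(self):
        cm = np.ones((50, 100), dtype=bool)
        sk = mm.skeletonize(_tm(np.zeros_like(cm)))
        assert mm.length_density(sk, cm) == 0.0

    def test_simple_arithmetic(self):
        cm = np.zeros((100, 50), dtype=bool)
        cm[:100, :50] = True  # 5000 px cell
        mask = np.zeros_like(cm)
        mask[10, 0:50] = True
        mask[30, 0:50] = True  # two 1-px lines, 100 skeleton px
        sk = mm.skeletonize(_tm(mask))
        assert mm.length_density(sk, cm) == pytest.approx(2.0, abs=0.05)

    def test_diagonal_correction_increases_length(self):
        mask = np.zeros((40, 40), dtype=bool)
        for i in range(30):
            mask[5 + i, 5 + i] = True  # pure diagonal line
        sk = mm.skeletonize(_tm(mask))
        plain = mm.skeleton_length(sk, diagonal_correction=False)
        geo = mm.skeleton_length(sk, diagonal_correction=True)
        assert geo == pytest.approx(plain * np.sqrt(2.0), rel=0.05)


class TestLocalOrientation:
    def test_horizontal_branch_is_90(self):
        path = [(10, c) for c in range(5, 35)]
        angles = mm.local_orientation(np.array(path))
        assert np.allclose(angles, 90.0)

    def test_vertical_branch_is_0(self):
        path = [(r, 10) for r in range(5, 35)]
        angles = mm.local_orientation(np.array(path))
        assert np.allclose(angles, 0.0)

    @pytest.mark.parametrize("dr,dc", [(2, 1), (1, 1), (1, 2), (3, 1)])
    def test_bresenham_lines_match_brute_force_chords(self, dr, dc):
        from skimage.draw import line

        rr, cc = line(5, 5, 5 + dr * 12, 5 + dc * 12)
        path = list(zip(rr.tolist(), cc.tolist()))
        angles = mm.local_orientation(np.array(path), window=7)
        oracle = chord_angles_on_path(path, half_window=3)
        interior = slice(4, -4)
        assert np.all(np.abs(angles[interior] - oracle[interior]) <= 4.0)
        expected = np.degrees(np.arctan2(dc, dr))
        assert np.all(np.abs(angles[interior] - expected) <= 4.0)

    def test_redundant_staircase_still_reads_45(self):
        """An orthogonal-step 45-degree staircase (which digital thinning
        would normally reduce to a diagonal) carries shortcut adjacencies;
        the geodesic chord still reads ~45 degrees at nearly every pixel,
        with at most a one-pixel-wide excursion bounded by 6 degrees."""
        path = []
        r, c = 5, 5
        for i in range(40):
            path.append((r, c))
            if i % 2 == 0:
                r += 1
            else:
                c += 1
        angles = mm.local_orientation(np.array(path), window=7)
        interior = angles[4:-4]
        dev = np.abs(interior - 45.0)
        assert np.mean(dev <= 4.0) >= 0.9
        assert dev.max() <= 6.0


class TestTransverseFraction:
    def test_band_membership(self):
        assert mm.transverse_fraction(np.full(50, 90.0)) == 100.0
        assert mm.transverse_fraction(np.full(50, 0.0)) == 0.0
        # band is inclusive at both printed endpoints
        assert mm.transverse_fraction(np.array([60.0, 130.0])) == 100.0
        assert mm.transverse_fraction(np.array([59.9, 130.1])) == 0.0

    def test_empty_skeleton_reports_missing(self):
        assert mm.transverse_fraction(np.empty(0)) is None

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError):
            mm.transverse_fraction(np.array([90.0]), band=(130.0, 60.0))

    def test_complement_sums_to_100(self, rng):
        angles = rng.uniform(0, 180, size=500)
        inside = mm.transverse_fraction(angles)
        outside = 100.0 * np.mean((angles < 60) | (angles > 130))
        assert inside + outside == pytest.approx(100.0)


class TestThicknessRatio:
    @pytest.mark.parametrize("w", [2, 3, 5])
    def test_straight_bar_ratio_near_width(self, w):
        mask = np.zeros((30, 120), dtype=bool)
        mask[10 : 10 + w, 5:115] = True
        ratio = mm.thickness_ratio(_tm(mask), mm.skeletonize(_tm(mask)))
        assert ratio == pytest.approx(w, abs=0.5)

    def test_dilation_strictly_increases_ratio(self, default_cell):
        from scipy import ndimage as ndi

        _, tmask, _ = default_cell
        dilated = _tm(ndi.binary_dilation(tmask.mask))
        r0 = mm.thickness_ratio(tmask, mm.skeletonize(tmask))
        r1 = mm.thickness_ratio(dilated, mm.skeletonize(dilated))
        assert r1 > r0

    def test_empty_skeleton_is_missing(self):
        empty = _tm(np.zeros((5, 5)))
        assert mm.thickness_ratio(empty, mm.skeletonize(empty)) is None


class TestInvariants:
    def test_length_pct_never_exceeds_area_pct(self, default_cell):
        cell, tmask, _ = default_cell
        sk = mm.skeletonize(tmask)
        assert mm.length_density(sk, cell.cell_mask) <= mm.area_fraction(
            tmask, cell.cell_mask
        )

    def test_metrics_invariant_under_quarter_turn(self, default_cell):
        """Area/length are rotation-invariant; the transverse fraction is
        recovered when the band is re-expressed about the rotated axis."""
        cell, tmask, _ = default_cell
        cm90 = np.rot90(cell.cell_mask)
        tm90 = _tm(np.rot90(tmask.mask))
        assert mm.area_fraction(tm90, cm90) == mm.area_fraction(
            tmask, cell.cell_mask
        )
        sk = mm.skeletonize(tmask)
        sk90 = mm.skeletonize(tm90)
        # digital thinning is rotation-equivariant only approximately
        assert abs(sk.length_px - sk90.length_px) <= 0.01 * sk.length_px
        orig = mm.transverse_fraction(sk.orientations_deg, band=(60, 130))
        # after a quarter turn the transverse band maps to [0,40] U [150,180)
        ang = sk90.orientations_deg
        rotated_band = 100.0 * np.mean((ang <= 40.0) | (ang >= 150.0))
        assert rotated_band == pytest.approx(orig, abs=2.0)
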