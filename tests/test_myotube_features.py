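import numpy as np
import pytest

from myotubekit.errors import NoMatchError, OffMyotubeError
from myotubekit.myotube_features import (
    BranchPointSet,
    coverage,
    edit_branch_points,
    find_branch_points,
    measure_diameters,
    myotube_feature_summary,
    skeletonize_mask,
)
from myotubekit.nuclei import NucleusSet
from myotubekit.preprocessing import PixelCalibration

from conftest import labeled, ribbon_mask


def y_ribbon(shape=(200, 200), width=10):
    """Three arms meeting at one junction."""
    m = ribbon_mask(shape, 100, 100, 100, 20, width)
    m |= ribbon_mask(shape, 100, 100, 30, 170, width)
    m |= ribbon_mask(shape, 100, 100, 170, 170, width)
    return m


def h_ribbon(shape=(220, 220), width=10):
    """Two verticals and a crossbar: two junctions."""
    m = ribbon_mask(shape, 20, 60, 200, 60, width)
    m |= ribbon_mask(shape, 20, 160, 200, 160, width)
    m |= ribbon_mask(shape, 110, 60, 110, 160, width)
    return m


class TestSkeletonize:
    def test_solid_rectangle_gives_central_path(self):
        m = np.zeros((40, 120), dtype=bool)
        m[10:30, 10:110] = True  # 100x20 horizontal rectangle
        skel = skeletonize_mask(labeled(m))
        rows = skel.coordinates[:, 0]
        center = 19.5
        near_center = np.abs(rows - center) <= 1.5
        assert near_center.mean() >= 0.95

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_mask(labeled(np.zeros((20, 20))))
        assert len(skel) == 0

    def test_one_px_line_is_its_own_skeleton(self):
        m = np.zeros((20, 40), dtype=bool)
        m[10, 5:35] = True
        skel = skeletonize_mask(labeled(m))
        assert np.array_equal(skel.pixels, m)

    def test_skeleton_subset_of_foreground_and_idempotent(self, rng):
        m = ribbon_mask((150, 150), 20, 20, 130, 120, 14)
        mask = labeled(m)
        skel = skeletonize_mask(mask)
        assert not (skel.pixels & ~m).any()
        again = skeletonize_mask(labeled(skel.pixels))
        assert np.array_equal(again.pixels, skel.pixels)


class TestBranchPoints:
    def test_straight_ribbon_has_none(self):
        m = ribbon_mask((100, 200), 50, 10, 50, 190, 12)
        skel = skeletonize_mask(labeled(m))
        assert find_branch_points(skel).count == 0

    def test_y_ribbon_has_one_near_junction(self):
        skel = skeletonize_mask(labeled(y_ribbon()))
        pts = find_branch_points(skel, min_branch_length=5)
        assert pts.count == 1
        d = np.hypot(pts.points[0, 0] - 100, pts.points[0, 1] - 100)
        assert d <= 10

    def test_h_ribbon_has_two(self):
        skel = skeletonize_mask(labeled(h_ribbon()))
        pts = find_branch_points(skel, min_branch_length=5)
        assert pts.count == 2

    def test_branch_points_lie_on_skeleton(self):
        skel = skeletonize_mask(labeled(y_ribbon()))
        pts = find_branch_points(skel)
        for r, c in pts.points.astype(int):
            assert skel.pixels[r, c]


class TestEditBranchPoints:
    def test_add_to_empty(self):
        out = edit_branch_points(BranchPointSet(np.empty((0, 2))), add=[(5, 5), (9, 9)])
        assert out.count == 2

    def test_remove_only_point(self):
        out = edit_branch_points(BranchPointSet(np.array([[5.0, 5.0]])), remove=[(5, 5)])
        assert out.count == 0

    def test_add_remove_roundtrip(self):
        base = BranchPointSet(np.array([[3.0, 4.0]]))
        out = edit_branch_points(
            edit_branch_points(base, add=[(20, 20)]), remove=[(20, 20)]
        )
        np.testing.assert_allclose(out.points, base.points)

    def test_remove_without_match_raises(self):
        with pytest.raises(NoMatchError):
            edit_branch_points(BranchPointSet(np.array([[3.0, 4.0]])), remove=[(90, 90)])


class TestCoverage:
    def test_full_mask_is_100_pct(self):
        rep = coverage(labeled(np.ones((10, 10))))
        assert rep.total_pct == pytest.approx(100.0)

    def test_half_mask_is_50_pct(self):
        m = np.zeros((10, 10), dtype=bool)
        m[:5] = True
        assert coverage(labeled(m)).total_pct == pytest.approx(50.0)

    def test_contributions_partition_total(self, rng):
        m = rng.random((80, 80)) < 0.3
        rep = coverage(labeled(m))
        assert rep.per_myotube_pct.sum() == pytest.approx(rep.total_pct, abs=1e-9)
        assert (rep.per_myotube_pct >= 0).all()


class TestDiameters:
    @pytest.mark.parametrize("width", [8, 14, 20, 30])
    def test_ribbon_width_recovered_within_2px(self, width):
        m = ribbon_mask((120, 300), 60, 20, 60, 280, width)
        mask = labeled(m)
        skel = skeletonize_mask(mask)
        # interior samples, away from round caps
        samples = [(60, c) for c in range(60, 241, 30)]
        measurements = measure_diameters(mask, skel, samples)
        ok = [abs(d.diameter_px - width) <= 2.0 for d in measurements]
        assert np.mean(ok) >= 0.9

    def test_diameter_is_twice_distance_transform_at_skeleton_point(self):
        from scipy.ndimage import distance_transform_edt

        m = ribbon_mask((100, 200), 50, 20, 50, 180, 16)
        mask = labeled(m)
        skel = skeletonize_mask(mask)
        dt = distance_transform_edt(m)
        (meas,) = measure_diameters(mask, skel, [(52, 100)])
        assert meas.diameter_px == pytest.approx(2 * dt[meas.skeleton_point])

    def test_off_center_sample_snaps_to_skeleton(self):
        """The measurement is taken at the snapped skeleton pixel, not the
        raw sample, so an imprecise click near the edge changes nothing."""
        m = ribbon_mask((100, 200), 50, 20, 50, 180, 20)
        mask = labeled(m)
        skel = skeletonize_mask(mask)
        center, edge = measure_diameters(mask, skel, [(50, 100), (57, 100)])
        assert edge.skeleton_point[0] == pytest.approx(center.skeleton_point[0], abs=1)
        assert edge.diameter_px == pytest.approx(center.diameter_px, abs=1.0)

    def test_microns_conversion(self):
        m = ribbon_mask((100, 200), 50, 20, 50, 180, 20)
        mask = labeled(m, mpp=0.5)
        skel = skeletonize_mask(mask)
        (meas,) = measure_diameters(mask, skel, [(50, 100)])
        assert meas.diameter_um == pytest.approx(meas.diameter_px * 0.5)

    def test_background_sample_rejected(self):
        m = ribbon_mask((100, 200), 50, 20, 50, 180, 10)
        mask = labeled(m)
        skel = skeletonize_mask(mask)
        with pytest.raises(OffMyotubeError, match="5"):
            measure_diameters(mask, skel, [(5, 5)])


class TestSummary:
    def test_totals_aggregate_per_myotube(self, calib):
        m = np.zeros((100, 260), dtype=bool)
        m[10:30, 10:250] = True
        m[60:80, 10:250] = True
        mask = labeled(m)
        pts = BranchPointSet(np.array([[20.0, 50.0], [70.0, 50.0], [70.0, 100.0]]))
        rep = coverage(mask)
        nuclei = NucleusSet(
            [(20.0, 20.0), (70.0, 20.0), (70.0, 40.0), (5.0, 5.0)],
            calib,
            in_myotube=[True, True, True, False],
            myotube_label=[1, 2, 2, 0],
        )
        s = myotube_feature_summary(mask, pts, rep, nuclei)
        assert s["n_myotubes"] == 2
        assert s["n_branch_points"] == 3
        assert s["branch_points_per_myotube"].tolist() == [1, 2]
        assert s["nuclei_per_myotube"].tolist() == [1, 2]
        assert s["coverage_pct"] == pytest.approx(rep.total_pct)

    def test_empty_mask_all_zero(self, calib):
        mask = labeled(np.zeros((50, 50)))
        s = myotube_feature_summary(
            mask, BranchPointSet(np.empty((0, 2))), coverage(mask), None
        )
        assert s["n_myotubes"] == 0
        assert s["n_branch_points"] == 0
        assert s["coverage_pct"] == 0.0
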