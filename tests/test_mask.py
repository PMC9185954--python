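import numpy as np
import pytest

from myotubekit.errors import InvalidEditError, InvalidParameterError, InvalidThresholdError
from myotubekit.mask import (
    Edit,
    EditScript,
    apply_edits,
    fill_holes,
    label_myotubes,
    remove_junk,
    threshold_mask,
)

from conftest import binary, channel
from oracles import component_areas, flood_fill_components, shoelace_area


class TestThreshold:
    def test_strict_inequality_at_zero(self):
        img = channel([[0.0, 0.01]])
        m = threshold_mask(img, 0.0)
        assert m.pixels.tolist() == [[False, True]]

    def test_uniform_below_threshold_is_empty(self):
        m = threshold_mask(channel(np.full((5, 5), 0.3)), 0.5)
        assert not m.pixels.any()

    def test_single_bright_pixel(self):
        img = np.full((3, 3), 0.1)
        img[1, 1] = 0.9
        m = threshold_mask(channel(img), 0.5)
        assert m.pixels.sum() == 1 and m.pixels[1, 1]

    def test_boundary_pixel_is_background(self):
        m = threshold_mask(channel([[0.5]]), 0.5)
        assert not m.pixels.any()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            threshold_mask(channel([[0.5]]), 1.2)


class TestRemoveJunk:
    @staticmethod
    def _blocks(areas):
        """Disjoint square-ish blocks with the requested pixel areas."""
        cols = sum(int(np.ceil(a / 40)) + 2 for a in areas)
        m = np.zeros((50, cols), dtype=bool)
        c = 0
        for a in areas:
            w = int(np.ceil(a / 40))
            block = np.zeros(40 * w, dtype=bool)
            block[:a] = True
            m[5:45, c : c + w] = block.reshape(40, w, order="F")
            c += w + 2
        return m

    def test_thousand_pixel_boundary(self):
        """Objects below 1000 px are junk; 1000 px exactly survives."""
        m = binary(self._blocks([999, 1000, 1500]))
        out = remove_junk(m, 1000)
        surviving = sorted(component_areas(out.pixels))
        assert surviving == [1000, 1500]

    def test_empty_mask_unchanged(self):
        out = remove_junk(binary(np.zeros((10, 10))), 1000)
        assert not out.pixels.any()

    def test_agrees_with_flood_fill_census(self, rng):
        """Survivors match an independent flood-fill area census."""
        blobs = rng.random((128, 128)) < 0.35
        m = binary(blobs)
        min_area = 20
        out = remove_junk(m, min_area)
        expected = sorted(a for a in component_areas(blobs) if a >= min_area)
        assert sorted(component_areas(out.pixels)) == expected

    def test_idempotent_and_never_adds(self, rng):
        m = binary(rng.random((64, 64)) < 0.4)
        once = remove_junk(m, 15)
        twice = remove_junk(once, 15)
        assert np.array_equal(once.pixels, twice.pixels)
        assert not (once.pixels & ~m.pixels).any()

    def test_invalid_min_area(self):
        with pytest.raises(InvalidParameterError):
            remove_junk(binary(np.zeros((4, 4))), 0)


class TestFillHoles:
    def test_ring_becomes_disk(self):
        m = np.zeros((9, 9), dtype=bool)
        m[2:7, 2:7] = True
        m[3:6, 3:6] = False
        out = fill_holes(binary(m))
        assert out.pixels[2:7, 2:7].all()
        assert out.pixels.sum() == 25

    def test_hole_free_mask_unchanged(self, rng):
        solid = np.zeros((20, 20), dtype=bool)
        solid[4:10, 4:16] = True
        out = fill_holes(binary(solid))
        assert np.array_equal(out.pixels, solid)

    def test_border_touching_cavity_not_filled(self):
        m = np.ones((6, 6), dtype=bool)
        m[0:4, 2] = False  # channel open to the top border
        out = fill_holes(binary(m))
        assert np.array_equal(out.pixels, m)

    def test_idempotent_and_never_removes(self, rng):
        m = binary(rng.random((64, 64)) < 0.5)
        once = fill_holes(m)
        twice = fill_holes(once)
        assert np.array_equal(once.pixels, twice.pixels)
        assert (once.pixels | ~m.pixels).all() or not (m.pixels & ~once.pixels).any()


class TestApplyEdits:
    def test_add_region_area_matches_shoelace(self):
        poly = [(10.0, 10.0), (10.0, 90.0), (70.0, 90.0), (70.0, 10.0)]
        script = EditScript([Edit("add_region", tuple(poly))])
        out = apply_edits(binary(np.zeros((100, 100))), script)
        analytic = shoelace_area(np.array(poly))
        assert abs(out.pixels.sum() - analytic) / analytic < 0.05

    def test_remove_region_whole_image(self):
        poly = [(0.0, 0.0), (0.0, 19.0), (19.0, 19.0), (19.0, 0.0)]
        out = apply_edits(
            binary(np.ones((20, 20))), EditScript([Edit("remove_region", tuple(poly))])
        )
        assert not out.pixels.any()

    def test_separate_line_splits_dumbbell(self):
        m = np.zeros((30, 60), dtype=bool)
        m[10:20, 5:25] = True
        m[10:20, 35:55] = True
        m[14:16, 25:35] = True  # neck
        assert label_myotubes(binary(m)).n_myotubes == 1
        script = EditScript([Edit("separate_line", ((5.0, 30.0), (25.0, 30.0)))])
        cut = apply_edits(binary(m), script)
        assert label_myotubes(cut).n_myotubes == 2

    def test_join_line_connects_components(self):
        m = np.zeros((20, 40), dtype=bool)
        m[8:12, 2:10] = True
        m[8:12, 30:38] = True
        script = EditScript([Edit("join_line", ((10.0, 5.0), (10.0, 35.0)))])
        joined = apply_edits(binary(m), script)
        assert label_myotubes(joined).n_myotubes == 1

    def test_edits_apply_in_order(self):
        poly = [(2.0, 2.0), (2.0, 17.0), (17.0, 17.0), (17.0, 2.0)]
        script = EditScript(
            [Edit("add_region", tuple(poly)), Edit("remove_region", tuple(poly))]
        )
        out = apply_edits(binary(np.zeros((20, 20))), script)
        assert not out.pixels.any()

    def test_out_of_bounds_vertex_names_edit_index(self):
        script = EditScript(
            [
                Edit("add_region", ((1.0, 1.0), (1.0, 3.0), (3.0, 3.0))),
                Edit("separate_line", ((0.0, 0.0), (99.0, 99.0))),
            ]
        )
        with pytest.raises(InvalidEditError, match="edit 1"):
            apply_edits(binary(np.zeros((10, 10))), script)

    def test_script_json_roundtrip(self, tmp_path):
        script = EditScript(
            [
                Edit("add_region", ((1.0, 1.0), (1.0, 5.0), (5.0, 5.0))),
                Edit("remove_junk", min_area=500),
                Edit("fill_holes"),
            ]
        )
        p = tmp_path / "edits.json"
        script.save(p)
        back = EditScript.load(p)
        assert back == script


class TestLabelMyotubes:
    def test_empty_mask_zero_objects(self):
        assert label_myotubes(binary(np.zeros((5, 5)))).n_myotubes == 0

    def test_two_disjoint_rectangles(self):
        m = np.zeros((10, 20), dtype=bool)
        m[2:5, 2:8] = True
        m[6:9, 12:18] = True
        labeled = label_myotubes(binary(m))
        assert labeled.n_myotubes == 2
        assert set(np.unique(labeled.labels)) == {0, 1, 2}

    def test_diagonal_touch_is_one_object(self):
        m = np.array([[1, 0], [0, 1]], dtype=bool)
        assert label_myotubes(binary(m)).n_myotubes == 1

    @pytest.mark.parametrize("density", [0.2, 0.45, 0.6])
    def test_count_matches_flood_fill_oracle(self, rng, density):
        blobs = rng.random((96, 96)) < density
        labeled = label_myotubes(binary(blobs))
        oracle = flood_fill_components(blobs, eight_connected=True)
        assert labeled.n_myotubes == oracle.max()
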