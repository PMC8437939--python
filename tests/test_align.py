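"""Segmentation and the three alignment methods."""

import numpy as np
import pytest
from skimage import transform as sktf

from softshape.align import (
    align,
    align_eem,
    align_extrema,
    align_manual,
    rotate_image,
    score_rotation,
    segment,
    _points_xy,
)
from softshape.geometry import rasterize_reference, reference_set, region_props


class TestSegment:
    def test_binary_input_unchanged_apart_from_hole_filling(self, refs_by_name):
        img = refs_by_name["pentagon"].image
        assert np.array_equal(segment(img), img)

    def test_interior_hole_is_filled(self, refs_by_name):
        solid = refs_by_name["circle"].image
        holed = solid.copy()
        holed[253:258, 253:258] = False
        assert segment(holed).sum() == solid.sum()

    def test_blank_image_raises(self):
        with pytest.raises(ValueError, match="blank"):
            segment(np.zeros((512, 512), dtype=np.uint8))

    def test_grayscale_otsu_segmentation(self, refs_by_name):
        img = refs_by_name["hexagon"].image
        gray = np.where(img, 200, 30).astype(np.uint8)
        out = segment(gray)
        assert np.array_equal(out, img)

    def test_border_artifact_removed(self, refs_by_name):
        img = refs_by_name["circle"].image.copy()
        img[0:3, :] = True  # artefact strip touching the border
        out = segment(img)
        assert out.sum() == refs_by_name["circle"].image.sum()

    def test_reframes_other_canvas_sizes(self):
        small = rasterize_reference("circle", side=43, canvas=128).image
        out = segment(small)
        assert out.shape == (512, 512)
        assert out.sum() == small.sum()


class TestRotateImage:
    def test_zero_angle_identity(self, refs_by_name):
        img = refs_by_name["triangle"].image
        assert np.array_equal(rotate_image(img, 0.0), img)

    def test_full_turn_identity(self, refs_by_name):
        img = refs_by_name["pentagon"].image
        out = rotate_image(img, 360.0)
        assert (out != img).mean() <= 0.005

    def test_quarter_turn_swaps_box_dimensions(self, refs_by_name):
        from softshape.deform import apply_elongation
        img = apply_elongation(refs_by_name["rectangle"].image, "horizontal", 1.4)
        p0 = region_props(img)
        p = region_props(rotate_image(img, 90.0))
        assert abs(p.bbox_length - p0.bbox_width) <= 1
        assert abs(p.bbox_width - p0.bbox_length) <= 1


class TestAlignEEM:
    def test_already_aligned_ellipse(self, refs_by_name):
        from softshape.deform import apply_elongation
        img = apply_elongation(refs_by_name["circle"].image, "horizontal", 1.5)
        res = align_eem(img)
        assert abs((res.angle + 180) % 360 - 180) <= 1.0

    def test_tilted_ellipse_realigned(self, refs_by_name):
        from softshape.deform import apply_elongation
        ellipse = apply_elongation(refs_by_name["circle"].image, "horizontal", 1.5)
        tilted = rotate_image(ellipse, 30.0)
        res = align_eem(tilted)
        assert region_props(res.aligned).alpha_ellipse < 1.0

    def test_circle_flagged_degenerate(self, refs_by_name):
        res = align_eem(refs_by_name["circle"].image)
        assert res.degenerate and res.angle == 0.0


class TestAlignExtrema:
    def test_axis_aligned_square_needs_no_rotation(self, refs, refs_by_name):
        res = align_extrema(refs_by_name["rectangle"].image, refs)
        assert res.angle % 90.0 == pytest.approx(0.0, abs=1.0)

    def test_rotated_square_recovered_mod_90(self, refs, refs_by_name):
        img = rotate_image(refs_by_name["rectangle"].image, 37.0)
        res = align_extrema(img, refs)
        assert (res.angle - (-37.0)) % 90.0 == pytest.approx(0.0, abs=1.5) or \
               (res.angle - (-37.0)) % 90.0 == pytest.approx(90.0, abs=1.5)

    def test_at_most_four_candidates(self, refs, refs_by_name, rng):
        for ref in refs_by_name.values():
            img = rotate_image(ref.image, float(rng.uniform(0, 360)))
            res = align_extrema(img, refs)
            assert 1 <= len(res.candidates) <= 4


class TestAlignManual:
    def test_reference_attains_near_zero_objective(self, refs, refs_by_name):
        res = align_manual(refs_by_name["hexagon"].image, refs)
        assert res.objective <= 1.0
        assert res.angle % 60.0 == pytest.approx(0.0, abs=1.0) or \
               res.angle % 60.0 == pytest.approx(60.0, abs=1.0)

    def test_never_worse_than_extrema(self, refs, refs_by_name, rng):
        # the extrema candidates are rounded onto the manual grid, so the
        # exhaustive scan can only improve the objective
        for ref in refs_by_name.values():
            img = rotate_image(ref.image, float(rng.uniform(0, 360)))
            assert align_manual(img, refs).objective <= \
                align_extrema(img, refs).objective + 1e-9

    def test_matches_independent_exhaustive_rescan(self):
        # oracle: literal loop over whole-degree rotations of the image
        # itself (skimage rotation, not the coordinate shortcut)
        refs = reference_set()
        img = rotate_image(rasterize_reference("pentagon").image, 23.0)
        objectives = []
        for delta in range(360):
            rot = sktf.rotate(img.astype(float), delta, order=0) > 0.5
            scores = score_rotation(_points_xy(rot), 0.0, refs)
            objectives.append(min(scores.values()))
        oracle_best = min(objectives)
        res = align_manual(img, refs)
        assert res.objective == pytest.approx(oracle_best, abs=0.35)
        near = {d for d, o in enumerate(objectives) if o <= oracle_best + 0.5}
        assert any(abs((res.angle - d + 180) % 360 - 180) <= 1 for d in near)


class TestDispatch:
    def test_none_returns_input(self, refs, refs_by_name):
        res = align(refs_by_name["circle"].image, "none", refs)
        assert res.angle == 0.0 and np.array_equal(res.aligned, refs_by_name["circle"].image)

    def test_unknown_method_rejected(self, refs, refs_by_name):
        with pytest.raises(ValueError, match="method"):
            align(refs_by_name["circle"].image, "best", refs)

    @pytest.mark.parametrize("method", ["eem", "extrema", "manual"])
    def test_alignment_preserves_area_within_2_percent(self, refs, refs_by_name, method):
        img = rotate_image(refs_by_name["triangle"].image, 100.0)
        res = align(img, method, refs)
        assert res.aligned.sum() == pytest.approx(img.sum(), rel=0.02)
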