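"""Deformation operators and the labeled-corpus generator."""

import numpy as np
import pytest

from softshape.deform import (
    DEFAULT_PATTERN_COUNTS,
    PATTERN_CODES,
    DeformationLabel,
    apply_elongation,
    apply_swelling,
    apply_warp,
    compose_and_orient,
    default_config,
    generate_corpus,
    radial_warp_law,
    sample_label,
)
from softshape.geometry import region_props


class TestIdentityLaws:
    def test_swelling_identity(self, refs_by_name):
        img = refs_by_name["pentagon"].image
        assert np.array_equal(apply_swelling(img, 1.0), img)

    @pytest.mark.parametrize("axis", ["horizontal", "vertical"])
    def test_elongation_identity(self, refs_by_name, axis):
        img = refs_by_name["triangle"].image
        assert np.array_equal(apply_elongation(img, axis, 1.0), img)

    @pytest.mark.parametrize("sign", ["convex", "concave"])
    def test_warp_zero_is_identity(self, refs_by_name, sign):
        img = refs_by_name["hexagon"].image
        assert np.array_equal(apply_warp(img, 0.0, sign), img)

    def test_neutral_label_reproduces_reference(self, refs_by_name):
        ref = refs_by_name["circle"]
        out = compose_and_orient(ref, DeformationLabel(pattern="0,0,0,0,0"))
        assert np.array_equal(out, ref.image)


class TestAffineScaling:
    def test_swelling_area_ratio(self, refs_by_name):
        img = refs_by_name["circle"].image
        out = apply_swelling(img, 1.2)
        assert out.sum() / img.sum() == pytest.approx(1.44, rel=0.02)

    def test_swelling_round_trip_area(self, refs_by_name):
        img = refs_by_name["circle"].image
        out = apply_swelling(apply_swelling(img, 0.5), 2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=0.05)

    def test_horizontal_elongation_changes_length_only(self, refs_by_name):
        img = refs_by_name["rectangle"].image
        p0 = region_props(img)
        p = region_props(apply_elongation(img, "horizontal", 1.5))
        assert p.bbox_length / p0.bbox_length == pytest.approx(1.5, abs=0.03)
        assert abs(p.bbox_width - p0.bbox_width) <= 1

    def test_vertical_elongation_keeps_horizontal_length(self, refs_by_name):
        img = refs_by_name["rectangle"].image
        p0 = region_props(img)
        p = region_props(apply_elongation(img, "vertical", 0.7))
        assert abs(p.bbox_length - p0.bbox_length) <= 1

    def test_oversized_scaling_raises(self, refs_by_name):
        with pytest.raises(ValueError, match="canvas"):
            apply_swelling(refs_by_name["rectangle"].image, 6.0)

    def test_nonpositive_factor_raises(self, refs_by_name):
        with pytest.raises(ValueError):
            apply_swelling(refs_by_name["circle"].image, 0.0)


class TestRadialWarp:
    def test_law_displacement_at_max_radius(self):
        # substituting d = max(d) gives a displacement of exactly S*max(d)
        d_max = 48.0
        assert radial_warp_law(d_max, 0.2, d_max) - d_max == pytest.approx(0.2 * d_max)

    def test_convex_raises_extent_ellipse(self, refs_by_name):
        for name in ("triangle", "rectangle"):
            img = refs_by_name[name].image
            p0 = region_props(img)
            p = region_props(apply_warp(img, 0.2, "convex"))
            assert p.extent_ellipse > p0.extent_ellipse

    def test_concave_lowers_extent_ellipse(self, refs_by_name):
        for name in ("triangle", "rectangle"):
            img = refs_by_name[name].image
            p0 = region_props(img)
            p = region_props(apply_warp(img, 0.2, "concave"))
            assert p.extent_ellipse < p0.extent_ellipse

    @pytest.mark.parametrize("sign", ["convex", "concave"])
    def test_extent_ellipse_monotone_in_s(self, refs_by_name, sign):
        img = refs_by_name["triangle"].image
        ee = [region_props(apply_warp(img, s, sign)).extent_ellipse
              for s in (0.05, 0.15, 0.25, 0.35)]
        diffs = np.diff(ee)
        assert np.all(diffs > 0) if sign == "convex" else np.all(diffs < 0)

    @pytest.mark.parametrize("preserve", ["none", "area"])
    def test_radial_warp_keeps_centroid(self, refs_by_name, preserve):
        for name in ("triangle", "pentagon"):
            img = refs_by_name[name].image
            c0 = region_props(img).centroid
            for sign in ("convex", "concave"):
                c1 = region_props(apply_warp(img, 0.25, sign, preserve=preserve)).centroid
                assert np.hypot(c1[0] - c0[0], c1[1] - c0[1]) <= 2.0

    def test_bbox_mode_preserves_box(self, refs_by_name):
        img = refs_by_name["pentagon"].image
        p0 = region_props(img)
        for sign in ("convex", "concave"):
            p = region_props(apply_warp(img, 0.3, sign))
            assert abs(p.bbox_length - p0.bbox_length) <= 1
            assert abs(p.bbox_width - p0.bbox_width) <= 1

    def test_bad_sign_raises(self, refs_by_name):
        with pytest.raises(ValueError):
            apply_warp(refs_by_name["circle"].image, 0.1, "sideways")


class TestComposeAndOrient:
    def test_rotation_preserves_area(self, refs_by_name):
        ref = refs_by_name["pentagon"]
        base = compose_and_orient(ref, DeformationLabel(pattern="+,+,+,0,0", s_swell=1.2))
        rot = compose_and_orient(
            ref, DeformationLabel(pattern="+,+,+,0,0", s_swell=1.2, orientation=37.0)
        )
        assert rot.sum() == pytest.approx(base.sum(), rel=0.02)

    def test_horizontal_elongation_opens_triangle_apex(self, refs_by_name):
        # stretching an equilateral triangle horizontally widens the apex
        # angle 2*atan(S*tan(30 deg)) beyond 90 degrees once S > sqrt(3)
        ref = refs_by_name["triangle"]
        out = compose_and_orient(
            ref, DeformationLabel(pattern="+,+,0,0,1", s_hx=2.0)
        )
        p = region_props(out)
        apex = 2 * np.degrees(np.arctan((p.bbox_length / 2) / p.bbox_width))
        assert apex > 90.0

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            DeformationLabel(pattern="+,+,+,+,+")


class TestGenerateCorpus:
    def test_default_counts_match_benchmark_design(self):
        cfg = default_config()
        assert cfg["counts"] == DEFAULT_PATTERN_COUNTS
        assert sum(cfg["counts"].values()) == 4200

    def test_small_corpus_structure_and_determinism(self, tmp_path):
        cfg = default_config(0.02)
        m1 = generate_corpus(cfg, 7, tmp_path / "a")
        m2 = generate_corpus(cfg, 7, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert m1.drop(columns=["path"]).equals(m2.drop(columns=["path"]))
        assert set(m1["pattern"]) == set(PATTERN_CODES)
        # equal per-shape counts within every pattern row
        per = m1.groupby(["pattern", "shape"]).size().groupby("pattern").nunique()
        assert (per == 1).all()

    def test_sampled_factors_within_configured_ranges(self, rng):
        cfg = default_config()
        for pattern in PATTERN_CODES:
            lab = sample_label(pattern, rng, cfg)
            for s in (lab.s_swell, lab.s_hx, lab.s_vx):
                assert s == 1.0 or 0.6 <= s <= 1.4
            if lab.warp_sign != "none":
                assert 0.05 <= lab.s_warp <= 0.35
            assert 0.0 <= lab.orientation < 360.0
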