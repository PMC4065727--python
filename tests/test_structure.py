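"""Layered porosity, layer schemes, interconnectivity, projection measures."""
import numpy as np
import pytest

from nanomat import (
    BinaryMask,
    GrayscaleImage,
    LayeredPorosityProfile,
    binarize,
    build_layer_scheme,
    fiber_diameters,
    intensity_histogram,
    interconnectivity,
    layered_porosity,
    max_feret,
    otsu_threshold,
    overall_porosity,
    porosity_profile,
    segment_pores,
    structural_summary,
)
from nanomat.config import AnalysisConfig

from conftest import make_hist


class TestLayeredPorosity:
    def test_above_supremum_everything_open(self, two_level_hist):
        assert layered_porosity(two_level_hist, 201) == 100.0

    def test_at_infimum_everything_solid(self, two_level_hist):
        assert layered_porosity(two_level_hist, 50) == 0.0

    def test_mid_threshold_counts_bright_pixels(self, two_level_hist):
        # 60 pixels at level 200 are >= 100 -> 100 * (1 - 60/100)
        assert layered_porosity(two_level_hist, 100) == pytest.approx(40.0)


class TestLayerScheme:
    def test_default_seven_layer_thresholds(self):
        h = make_hist(mu=128, sigma=30, a=10, b=250)
        s = build_layer_scheme(h, 7)
        assert s.thresholds == (188.0, 158.0, 128.0, 98.0, 68.0, 10.0)
        assert not s.reduced

    def test_wide_sigma_clips_to_reduced_scheme(self):
        h = make_hist(mu=128, sigma=200, a=0, b=255)
        s = build_layer_scheme(h, 7)
        assert s.thresholds == (128.0, 0.0)
        assert s.reduced

    def test_constant_image_is_degenerate(self):
        h = intensity_histogram(GrayscaleImage(np.full((4, 4), 9, dtype=np.uint8)))
        with pytest.raises(ValueError, match="constant image"):
            build_layer_scheme(h, 7)

    def test_fewer_layers_requested(self):
        h = make_hist(mu=100, sigma=20, a=5, b=240)
        assert build_layer_scheme(h, 3).thresholds == (100.0, 5.0)
        with pytest.raises(ValueError):
            build_layer_scheme(h, 1)


class TestPorosityProfile:
    def test_two_level_profile_values(self, two_level_hist):
        from nanomat.structure import LayerScheme

        scheme = LayerScheme(thresholds=(200.0, 100.0, 50.0), n_requested=3)
        prof = porosity_profile(two_level_hist, scheme)
        assert prof.entries == ((200.0, 40.0), (100.0, 40.0), (50.0, 0.0))

    def test_uniform_histogram_profile(self):
        # equal counts at all 256 levels: P_xb = 100 * (1 - (256 - x)/256)
        px = np.tile(np.arange(256, dtype=np.uint8), 4).reshape(32, 32)
        h = intensity_histogram(GrayscaleImage(px))
        from nanomat.structure import LayerScheme

        scheme = LayerScheme(thresholds=(192.0, 128.0, 64.0, 0.0), n_requested=4)
        prof = porosity_profile(h, scheme)
        assert prof.porosities == (75.0, 50.0, 25.0, 0.0)

    def test_terminal_entry_at_infimum_is_zero(self, two_level_hist):
        scheme = build_layer_scheme(two_level_hist, 7)
        prof = porosity_profile(two_level_hist, scheme)
        assert prof.porosities[-1] == 0.0
        assert all(p1 >= p2 for p1, p2 in zip(prof.porosities, prof.porosities[1:]))


class TestInterconnectivity:
    def test_exact_linear_profile(self):
        prof = LayeredPorosityProfile(
            thresholds=tuple(range(6, 0, -1)),
            porosities=(100.0, 80.0, 60.0, 40.0, 20.0, 0.0),
        )
        fit = interconnectivity(prof)
        assert fit.slope == pytest.approx(-20.0)
        assert fit.H == pytest.approx(20.0)
        assert fit.interconnectivity_index == pytest.approx(0.05)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.interconnectivity_index * fit.H == pytest.approx(1.0, abs=1e-9)

    def test_flat_profile_is_undefined(self):
        prof = LayeredPorosityProfile(
            thresholds=(3.0, 2.0, 1.0), porosities=(30.0, 30.0, 30.0)
        )
        fit = interconnectivity(prof)
        assert fit.H == 0.0 and not fit.defined

    def test_three_point_closed_form(self):
        # OLS slope of (1,90),(2,70),(3,20) is -35
        prof = LayeredPorosityProfile(
            thresholds=(3.0, 2.0, 1.0), porosities=(90.0, 70.0, 20.0)
        )
        fit = interconnectivity(prof)
        assert fit.H == pytest.approx(35.0)
        assert fit.interconnectivity_index == pytest.approx(1 / 35)

    def test_too_few_layers(self):
        prof = LayeredPorosityProfile(thresholds=(2.0, 1.0), porosities=(10.0, 0.0))
        with pytest.raises(ValueError, match="3 layers"):
            interconnectivity(prof)


class TestBinarize:
    def test_otsu_separates_perfectly_bimodal(self):
        px = np.indices((8, 8)).sum(axis=0) % 2 * 255
        mask = binarize(GrayscaleImage(px.astype(np.uint8)), method="otsu")
        np.testing.assert_array_equal(mask.solid, px == 255)

    def test_fixed_threshold(self, two_level_image):
        mask = binarize(two_level_image, method="fixed", level=100)
        assert int(mask.solid.sum()) == 60

    def test_otsu_constant_image_fails(self):
        with pytest.raises(ValueError, match="bimodality"):
            binarize(GrayscaleImage(np.full((5, 5), 7, dtype=np.uint8)), method="otsu")

    def test_otsu_matches_brute_force_variance_argmax(self):
        from nanomat import default_mat_spec, render_mat

        img, _ = render_mat(default_mat_spec(seed=1, width=128, height=128))
        hist = intensity_histogram(img)
        px = img.pixels.ravel().astype(float)
        best_t, best_v = 0, -1.0
        for t in range(256):
            fg = px >= t
            w1 = fg.mean()
            if w1 in (0.0, 1.0):
                v = 0.0
            else:
                v = w1 * (1 - w1) * (px[fg].mean() - px[~fg].mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert otsu_threshold(hist) == best_t

    def test_otsu_mask_agrees_with_skimage(self):
        from skimage.filters import threshold_otsu

        from nanomat import default_mat_spec, render_mat

        img, _ = render_mat(default_mat_spec(seed=2, width=128, height=128))
        mine = binarize(img, method="otsu").solid
        np.testing.assert_array_equal(mine, img.pixels > threshold_otsu(img.pixels))

    def test_invert_flag_flips_phase(self, two_level_image):
        mask = binarize(two_level_image, method="fixed", level=100)
        inv = binarize(two_level_image, method="fixed", level=255 - 100 + 1, invert=True)
        np.testing.assert_array_equal(inv.solid, ~mask.solid)


class TestOverallPorosity:
    def test_all_pore(self):
        mask = BinaryMask(solid=np.zeros((4, 4), bool), threshold_used=0)
        assert overall_porosity(mask) == 1.0

    def test_checkerboard(self):
        solid = (np.indices((6, 6)).sum(axis=0) % 2).astype(bool)
        assert overall_porosity(BinaryMask(solid=solid, threshold_used=0)) == 0.5

    def test_direct_count(self):
        solid = np.zeros(100, bool)
        solid[:37] = True
        mask = BinaryMask(solid=solid.reshape(10, 10), threshold_used=0)
        assert overall_porosity(mask) == pytest.approx(0.63)


class TestSegmentPores:
    def test_all_solid_gives_empty_list(self):
        mask = BinaryMask(solid=np.ones((6, 6), bool), threshold_used=0)
        assert segment_pores(mask) == []

    def test_interior_hole(self):
        solid = np.ones((7, 7), bool)
        solid[2:5, 2:5] = False
        regions = segment_pores(BinaryMask(solid=solid, threshold_used=0), min_area=5)
        assert len(regions) == 1
        assert regions[0].area == 9
        assert not regions[0].touches_border
        assert regions[0].max_feret == pytest.approx(2 * np.sqrt(2))

    def test_diagonal_pixels_are_separate_under_4_connectivity(self):
        solid = np.ones((5, 5), bool)
        solid[1, 1] = solid[2, 2] = False
        regions = segment_pores(
            BinaryMask(solid=solid, threshold_used=0), min_area=1
        )
        assert len(regions) == 2
        assert all(r.area == 1 and r.max_feret == 0.0 for r in regions)

    def test_border_policy(self):
        solid = np.ones((6, 6), bool)
        solid[0, 0:3] = False  # pore touching the frame edge
        mask = BinaryMask(solid=solid, threshold_used=0)
        assert segment_pores(mask, min_area=1, border_policy="exclude") == []
        inc = segment_pores(mask, min_area=1, border_policy="include")
        assert len(inc) == 1 and inc[0].touches_border

    def test_min_area_drops_specks(self):
        solid = np.ones((9, 9), bool)
        solid[1, 1] = False  # 1-px speck
        solid[4:7, 4:7] = False  # 9-px pore
        regions = segment_pores(BinaryMask(solid=solid, threshold_used=0), min_area=5)
        assert [r.area for r in regions] == [9]


class TestMaxFeret:
    def test_single_pixel_zero(self):
        solid = np.ones((4, 4), bool)
        solid[1, 1] = False
        (r,) = segment_pores(BinaryMask(solid=solid, threshold_used=0), min_area=1)
        assert max_feret(r) == 0.0

    def test_horizontal_run(self):
        solid = np.ones((5, 9), bool)
        solid[2, 2:7] = False  # 5 collinear pore pixels
        (r,) = segment_pores(BinaryMask(solid=solid, threshold_used=0), min_area=1)
        assert max_feret(r) == pytest.approx(4.0)

    def test_three_four_five_triangle(self):
        from nanomat.structure import _max_feret_points

        pts = np.array([[0, 0], [0, 1], [1, 0], [3, 4]])
        assert _max_feret_points(pts) == pytest.approx(5.0)


class TestFiberDiameters:
    def test_constant_width_band_measures_exactly(self):
        solid = np.zeros((20, 60), bool)
        solid[6:13, :] = True  # height-7 band spanning the frame
        stats = fiber_diameters(BinaryMask(solid=solid, threshold_used=0), 50, seed=0)
        assert stats.measurements == tuple([7.0] * 50)

    def test_single_pixel_band(self):
        solid = np.zeros((9, 40), bool)
        solid[4, :] = True
        stats = fiber_diameters(BinaryMask(solid=solid, threshold_used=0), 20, seed=1)
        assert stats.mean == pytest.approx(1.0)
        assert stats.sd == 0.0

    def test_resampling_flagged_when_skeleton_is_small(self):
        solid = np.zeros((7, 7), bool)
        solid[3, 2:5] = True
        stats = fiber_diameters(BinaryMask(solid=solid, threshold_used=0), 100, seed=0)
        assert stats.resampled and stats.n_measurements == 100

    def test_empty_and_full_masks_fail(self):
        with pytest.raises(ValueError):
            fiber_diameters(BinaryMask(solid=np.zeros((5, 5), bool), threshold_used=0))
        with pytest.raises(ValueError):
            fiber_diameters(BinaryMask(solid=np.ones((5, 5), bool), threshold_used=0))


class TestStructuralSummary:
    def test_spe_identity_and_stage_flow(self):
        from nanomat import default_mat_spec, render_mat

        img, _ = render_mat(default_mat_spec(seed=0, width=160, height=160))
        s = structural_summary(img, AnalysisConfig())
        assert s.fit.defined
        assert s.SPE * s.fit.H == pytest.approx(s.P_percent, abs=1e-9)
        assert 0.0 <= s.P_fraction <= 1.0
        assert s.profile.porosities[-1] == 0.0

    def test_constant_image_fails_at_layer_scheme(self):
        img = GrayscaleImage(np.full((16, 16), 90, dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\[build_layer_scheme\].*constant"):
            structural_summary(img, AnalysisConfig())

    def test_nm_conversion(self):
        from nanomat import default_mat_spec, render_mat

        img, _ = render_mat(default_mat_spec(seed=3, width=160, height=160))
        row = structural_summary(img, AnalysisConfig(nm_per_pixel=25.0)).as_row()
        assert row["fiber_mean_nm"] == pytest.approx(row["fiber_mean_px"] * 25.0)
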