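"""Synthetic mat renderer and viability generator."""
import numpy as np
import pytest

from nanomat import (
    MatSpec,
    binarize,
    default_mat_spec,
    overall_porosity,
    render_mat,
    sample_structural_metrics,
    simulate_viability,
    viability_stats,
)
from nanomat.compare import pearson_r


class TestRenderMat:
    def test_zero_fibers_is_uniform_background(self):
        spec = MatSpec(width=40, height=30, n_depth_layers=2, fibers_per_layer=0,
                       layer_intensities=(200, 100), background_level=17,
                       blur_sigma=0.0, noise_sd=0.0)
        img, truth = render_mat(spec)
        assert (img.pixels == 17).all()
        assert truth.true_porosity == 1.0

    def test_single_horizontal_fiber_coverage(self):
        # force a horizontal fiber through the frame center by shrinking
        # the random placement to a single layer and checking the union area
        spec = MatSpec(width=100, height=100, n_depth_layers=1, fibers_per_layer=1,
                       fiber_diameter_mean=5.0, fiber_diameter_sd=0.0,
                       layer_intensities=(200,), background_level=0,
                       blur_sigma=0.0, noise_sd=0.0, seed=11)
        img, truth = render_mat(spec)
        covered_px = (1.0 - truth.true_porosity) * 100 * 100
        # band area ~ diameter x chord length; the chord of a random line
        # through an interior point is bounded by the frame diagonal
        assert 0 < covered_px <= 5 * 100 * np.sqrt(2) + 100
        assert covered_px == pytest.approx(round(covered_px))  # integral pixel count
        assert truth.true_diameters == (5.0,)

    def test_exact_band_area_for_axis_aligned_fiber(self, monkeypatch):
        from nanomat.structure import BinaryMask
        from nanomat.synthetic import _fiber_mask

        band = _fiber_mask((100, 100), row0=50.0, col0=13.0, theta=0.0, diameter=5.0)
        assert int(band.sum()) == 500  # 5 rows x 100 columns

    def test_determinism(self):
        spec = default_mat_spec(seed=5, width=96, height=96)
        img1, t1 = render_mat(spec)
        img2, t2 = render_mat(spec)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        assert t1 == t2

    def test_cumulative_coverage_monotone_and_consistent(self):
        _, truth = render_mat(default_mat_spec(seed=2, width=96, height=96))
        cov = truth.per_layer_cumulative_coverage
        assert all(c1 <= c2 for c1, c2 in zip(cov, cov[1:]))
        assert truth.true_porosity == pytest.approx(1.0 - cov[-1])

    def test_imaging_fidelity_without_blur_or_noise(self):
        spec = MatSpec(width=128, height=128, n_depth_layers=1, target_coverage=0.3,
                       fiber_diameter_mean=6.0, layer_intensities=(220,),
                       background_level=20, blur_sigma=0.0, noise_sd=0.0, seed=3)
        img, truth = render_mat(spec)
        mask = binarize(img, method="fixed", level=120)
        assert overall_porosity(mask) == pytest.approx(truth.true_porosity, abs=0)

    def test_unreachable_coverage_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            MatSpec(width=10, height=10, target_coverage=0.999)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            MatSpec(fibers_per_layer=3, target_coverage=0.5)
        with pytest.raises(ValueError, match="strictly decrease"):
            MatSpec(fibers_per_layer=1, n_depth_layers=2, layer_intensities=(100, 100))


class TestSimulateViability:
    def test_single_positive_weight_gives_perfect_correlation(self):
        metrics = sample_structural_metrics(8, seed=0)
        table = simulate_viability(metrics, {"fiber_mean": 10.0}, noise_sd=0.0, seed=0)
        stats = viability_stats(table)
        via = [s.mean_relative_viability for s in stats]
        assert pearson_r(metrics["fiber_mean"].to_numpy(), via) == pytest.approx(1.0)

    def test_zero_weights_collapse_to_intercept(self):
        metrics = sample_structural_metrics(5, seed=1)
        table = simulate_viability(metrics, {}, noise_sd=0.0, seed=0, intercept=75.0)
        stats = viability_stats(table)
        assert all(
            s.mean_relative_viability == pytest.approx(75.0) for s in stats
        )

    def test_three_replicates_and_controls_per_sample(self):
        metrics = sample_structural_metrics(4, seed=2)
        table = simulate_viability(metrics, {"P": -3.0}, seed=9)
        assert len(table.frame) == 4
        assert list(table.frame.columns) == [
            "sample_id", "abs_1", "abs_2", "abs_3", "ctrl_1", "ctrl_2", "ctrl_3"
        ]
        assert (table.frame.iloc[:, 1:] > 0).all().all()

    def test_nonpositive_control_rejected(self):
        metrics = sample_structural_metrics(4, seed=0)
        with pytest.raises(ValueError, match="control_mean"):
            simulate_viability(metrics, {}, control_mean=0.0)


class TestSampleStructuralMetrics:
    def test_ranges_and_trend_structure(self):
        m = sample_structural_metrics(200, seed=0)
        assert m["fiber_mean"].between(140, 350).all()
        assert m["P"].between(0.02, 0.6).all()
        # electrospinning trend: coarser fibers, bigger pores, lower porosity
        assert pearson_r(m["fiber_mean"], m["pore_mean"]) > 0.8
        assert pearson_r(m["fiber_mean"], m["P"]) < -0.8
        assert pearson_r(m["fiber_mean"], m["interconnectivity_index"]) > 0.8
        assert pearson_r(m["fiber_mean"], m["SPE"]) < -0.8
        # SPE is consistent with its definition P(percent) / H
        np.testing.assert_allclose(
            m["SPE"], 100 * m["P"] * m["interconnectivity_index"], rtol=1e-12
        )
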