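"""Synthetic micrograph generator: sampling, rendering, presets, file I/O."""

import numpy as np
import pytest
from scipy.special import iv

from cytostretch.alignment_stats import alignment_metrics
from cytostretch.cell_metrics import segment_nuclei
from cytostretch.synthetic_data import (
    CONDITION_PRESETS,
    FiberFieldSpec,
    NucleiFieldSpec,
    OrientationDistribution,
    generate_condition,
    read_image,
    render_background_only,
    render_fibers,
    render_nuclei,
    sample_axial_angles,
    write_synthetic,
)


class TestSampling:
    def test_uniform_sample_has_near_zero_ci(self):
        angles = sample_axial_angles(OrientationDistribution("uniform"), 100_000, 5)
        assert alignment_metrics(angles).coherency_index_CI < 0.02

    def test_degenerate_concentration_collapses_to_mean(self):
        dist = OrientationDistribution("axial_von_mises", mu_deg=37.0, kappa=1e6)
        angles = sample_axial_angles(dist, 100, 5)
        dev = np.minimum(np.abs(angles - 37.0), 180.0 - np.abs(angles - 37.0))
        assert dev.max() < 0.5
        assert alignment_metrics(angles).coherency_index_CI > 0.999

    @pytest.mark.parametrize("kappa", [0.515, 1.52, 3.64])
    def test_resultant_length_matches_bessel_ratio(self, kappa):
        dist = OrientationDistribution("axial_von_mises", kappa=kappa)
        angles = sample_axial_angles(dist, 100_000, 17)
        expected = iv(1, kappa) / iv(0, kappa)
        assert alignment_metrics(angles).resultant_length_R2 == pytest.approx(
            expected, abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_axial_angles(OrientationDistribution("uniform"), 0, 1)
        with pytest.raises(ValueError):
            OrientationDistribution("axial_von_mises", kappa=-1.0)

    def test_mu_wraps_modulo_180(self):
        assert OrientationDistribution("axial_von_mises", mu_deg=190.0).mu_deg == 10.0


class TestRenderFibers:
    def test_background_only_field_statistics(self):
        spec = FiberFieldSpec(image_shape_px=(128, 128), background_level=200.0,
                              noise_sd=10.0, fiber_amplitude=1000.0)
        img = render_background_only(spec, seed=2)
        assert img.mean() == pytest.approx(200.0, abs=1.0)
        assert img.std() == pytest.approx(10.0, abs=1.0)

    def test_single_horizontal_fiber_concentrates_in_a_row_band(self, small_fiber_spec):
        img = render_fibers(small_fiber_spec, [0.0], seed=9)
        row_profile = img.sum(axis=1)
        peak = int(np.argmax(row_profile))
        # everything beyond a few widths of the peak row is empty
        assert row_profile[peak] > 0
        far = np.r_[row_profile[: max(0, peak - 8)], row_profile[peak + 9:]]
        assert far.max() < 0.01 * row_profile[peak]

    def test_determinism_bit_identical(self, small_fiber_spec):
        a = render_fibers(small_fiber_spec, [30.0, 60.0], seed=4)
        b = render_fibers(small_fiber_spec, [30.0, 60.0], seed=4)
        np.testing.assert_array_equal(a, b)

    def test_overlong_fiber_warns_and_truncates(self):
        spec = FiberFieldSpec(image_shape_px=(64, 64), pixel_size_um=1.0,
                              fiber_length_um=(500.0, 0.0), noise_sd=0.0,
                              background_level=0.0)
        with pytest.warns(UserWarning, match="diagonal"):
            img = render_fibers(spec, [45.0], seed=1)
        assert np.all(np.isfinite(img))

    def test_intensity_linearity_after_background(self):
        spec = FiberFieldSpec(image_shape_px=(128, 128), n_fibers=5, noise_sd=0.0,
                              background_level=50.0, fiber_amplitude=500.0)
        spec2 = FiberFieldSpec(image_shape_px=(128, 128), n_fibers=5, noise_sd=0.0,
                               background_level=50.0, fiber_amplitude=1000.0)
        a = render_fibers(spec, [20.0] * 5, seed=6) - 50.0
        b = render_fibers(spec2, [20.0] * 5, seed=6) - 50.0
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FiberFieldSpec(fiber_amplitude=10.0, background_level=20.0)
        with pytest.raises(ValueError):
            FiberFieldSpec(noise_sd=-1.0)


class TestRenderNuclei:
    def test_zero_nuclei_yields_empty_ground_truth(self):
        spec = NucleiFieldSpec(image_shape_px=(128, 128), n_nuclei=0)
        img, gt = render_nuclei(spec, seed=3)
        assert gt.nuclei_areas_um2.size == 0
        assert img.shape == (128, 128)

    def test_fixed_area_nuclei_recovered_by_segmentation(self):
        spec = NucleiFieldSpec(image_shape_px=(256, 256), n_nuclei=10,
                               area_um2=(150.0, 0.0), noise_sd=0.0)
        img, gt = render_nuclei(spec, seed=8)
        assert gt.nuclei_areas_um2.size == 10
        count, _, _ = segment_nuclei(img, spec.pixel_size_um)
        assert count == 10

    def test_oversized_nucleus_rendered_but_gated_out(self):
        spec = NucleiFieldSpec(image_shape_px=(256, 256), n_nuclei=1,
                               area_um2=(600.0, 0.0), noise_sd=0.0)
        img, gt = render_nuclei(spec, seed=8)
        assert gt.nuclei_areas_um2[0] == pytest.approx(600.0, rel=0.05)
        count, _, _ = segment_nuclei(img, spec.pixel_size_um)
        assert count == 0

    def test_impossible_placement_warns_and_places_fewer(self):
        spec = NucleiFieldSpec(image_shape_px=(64, 64), pixel_size_um=1.0,
                               n_nuclei=50, area_um2=(400.0, 0.0))
        with pytest.warns(UserWarning, match="fewer"):
            _, gt = render_nuclei(spec, seed=1)
        assert gt.nuclei_areas_um2.size < 50


class TestPresets:
    @pytest.mark.parametrize("name, target", [
        ("control", 0.25),
        ("stretch_0p5Hz_10pct", 0.85),
        ("stretch_2p5Hz_1pct", 0.60),
    ])
    def test_ground_truth_ci_matches_preset_target(self, name, target):
        """Population CI of the preset's angle law equals the Bessel ratio."""
        kappa = CONDITION_PRESETS[name].orientation.kappa
        assert iv(1, kappa) / iv(0, kappa) == pytest.approx(target, abs=0.02)
        dist = CONDITION_PRESETS[name].orientation
        angles = sample_axial_angles(dist, 50_000, 1)
        assert alignment_metrics(angles).coherency_index_CI == pytest.approx(
            target, abs=0.02)

    def test_unknown_preset_rejected_with_valid_names(self):
        with pytest.raises(KeyError, match="control"):
            generate_condition("no_such_preset", seed=1)

    def test_generate_condition_is_deterministic(self, small_fiber_spec,
                                                 small_nuclei_spec):
        a = generate_condition("control", small_fiber_spec, small_nuclei_spec, seed=5)
        b = generate_condition("control", small_fiber_spec, small_nuclei_spec, seed=5)
        np.testing.assert_array_equal(a.actin_channel, b.actin_channel)
        np.testing.assert_array_equal(a.nuclei_channel, b.nuclei_channel)
        np.testing.assert_array_equal(a.ground_truth.fiber_angles_deg,
                                      b.ground_truth.fiber_angles_deg)

    def test_multipliers_scale_amplitude_and_counts(self, small_fiber_spec,
                                                    small_nuclei_spec):
        img = generate_condition("stretch_0p5Hz_10pct", small_fiber_spec,
                                 small_nuclei_spec, seed=5)
        assert img.ground_truth.nuclei_areas_um2.size == 15  # 10 * 1.5


class TestIO:
    def test_write_read_round_trip(self, tmp_path, small_fiber_spec,
                                   small_nuclei_spec):
        img = generate_condition("control", small_fiber_spec, small_nuclei_spec,
                                 seed=2)
        out = write_synthetic(img, tmp_path / "set1")
        back = read_image(out)
        np.testing.assert_array_equal(
            back.actin_channel, np.round(np.clip(img.actin_channel, 0, 65535)))
        assert back.pixel_size_um == img.pixel_size_um
        assert back.preset == "control"
        # a second write of the read-back image is bit-stable
        out2 = write_synthetic(back, tmp_path / "set2")
        again = read_image(out2)
        np.testing.assert_array_equal(back.actin_channel, again.actin_channel)

    def test_png_promoted_to_float_with_values_preserved(self, tmp_path):
        import imageio.v3 as iio

        arr = (np.arange(64 * 64).reshape(64, 64) % 256).astype(np.uint8)
        p = tmp_path / "img.png"
        iio.imwrite(p, arr)
        img = read_image(p, pixel_size_um=0.5)
        assert img.actin_channel.dtype == float
        np.testing.assert_array_equal(img.actin_channel, arr.astype(float))

    def test_missing_pixel_size_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "img.tif"
        tifffile.imwrite(p, np.zeros((32, 32), dtype=np.uint16))
        with pytest.raises(ValueError):
            read_image(p)
        with pytest.raises(ValueError):
            read_image(p, pixel_size_um=0.0)
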