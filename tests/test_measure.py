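"""ROI placement and CNR measurement."""

import math

import numpy as np
import pytest

from icmreduce import (
    AcquisitionSetting,
    ConfigError,
    ContrastModel,
    DegenerateInputError,
    ImageVolume,
    NoiseModel,
    ROIStats,
    compute_cnr,
    dect_phantom,
    generate_noise_free,
    generate_phantom_image,
    locate_rois,
    measure_image,
    roi_stats,
)
from icmreduce.simulate import GridSpec, child_seed


def acq(energy=60.0, ctdi=10.0, size="small_adult"):
    return AcquisitionSetting("DECT-VMI", energy, "test", "ir", ctdi, size)


@pytest.fixture(scope="module")
def clean_volume(small_phantom, contrast):
    grid = GridSpec(pixel_spacing=1.0, n_slices=3)
    return generate_noise_free(small_phantom, acq(), contrast, grid)


class TestLocateROIs:
    def test_roi_mask_area_matches_brute_force_pixel_count(self, clean_volume, small_phantom):
        """Mask area equals the count of 1 mm pixel centres in the eroded disk."""
        layout = locate_rois(clean_volume, small_phantom, roi_fraction=0.7)
        ins = small_phantom.inserts[0]
        r = 0.7 * ins.diameter / 2.0
        X, Y = clean_volume.xy_grids()
        count = 0
        ny, nx = X.shape
        for i in range(ny):
            for j in range(nx):
                if (X[i, j] - ins.center_xy[0]) ** 2 + (Y[i, j] - ins.center_xy[1]) ** 2 <= r**2:
                    count += 1
        assert layout.insert_masks[0].sum() == count
        # and the count sits within one pixel-ring of the analytic area
        area = math.pi * r**2
        ring = 2 * math.pi * r * 1.0
        assert abs(count - area) <= ring

    def test_auto_mode_matches_geometry_within_one_pixel(self, clean_volume, small_phantom):
        geo = locate_rois(clean_volume, small_phantom, mode="geometry")
        auto = locate_rois(clean_volume, small_phantom, mode="auto")
        for (gx, gy), (ax, ay) in zip(geo.insert_centers, auto.insert_centers):
            assert math.hypot(gx - ax, gy - ay) <= clean_volume.pixel_spacing

    def test_background_rois_same_area_and_disjoint_from_inserts(self, clean_volume, small_phantom):
        layout = locate_rois(clean_volume, small_phantom)
        areas = {int(m.sum()) for m in layout.background_masks}
        assert len(layout.background_masks) == 4
        assert max(areas) - min(areas) <= 0.1 * max(areas)  # discretisation only
        for bg in layout.background_masks:
            for im in layout.insert_masks:
                assert not (bg & im).any()

    def test_explicit_background_offset_colliding_with_insert_errors(
        self, clean_volume, small_phantom
    ):
        bad = [small_phantom.inserts[0].center_xy]
        with pytest.raises(ConfigError):
            locate_rois(clean_volume, small_phantom, background_offsets=bad)

    def test_background_offset_outside_body_errors(self, clean_volume, small_phantom):
        with pytest.raises(ConfigError):
            locate_rois(clean_volume, small_phantom, background_offsets=[(98.0, 0.0)])

    def test_invalid_roi_fraction_rejected(self, clean_volume, small_phantom):
        with pytest.raises(ConfigError):
            locate_rois(clean_volume, small_phantom, roi_fraction=0.95)

    def test_auto_mode_names_missing_insert(self, small_phantom, contrast):
        """A zero-contrast insert cannot be detected; the error names it."""
        from icmreduce import DetectionError

        spec = small_phantom.with_concentrations([0.0, 5.0, 10.0, 15.0])
        grid = GridSpec(pixel_spacing=1.0, n_slices=3)
        vol = generate_noise_free(spec, acq(), contrast, grid)
        with pytest.raises(DetectionError, match="insert 0"):
            locate_rois(vol, spec, mode="auto")


class TestROIStats:
    def test_constant_image(self):
        vol = ImageVolume(np.full((2, 4, 4), 50.0), 1.0, 5.0)
        st = roi_stats(vol, np.ones((4, 4), bool), slice_policy=1.0)
        assert st.mean_hu == 50.0 and st.sd_hu == 0.0

    def test_hand_arithmetic_four_voxels(self):
        vol = ImageVolume(np.array([[[10.0, 10.0], [20.0, 20.0]]]), 1.0, 5.0)
        st = roi_stats(vol, np.ones((2, 2), bool), slice_policy=1.0)
        assert st.mean_hu == pytest.approx(15.0)
        assert st.sd_hu == pytest.approx(5.7735, abs=1e-4)
        assert st.n_voxels == 4

    def test_empty_slice_policy_errors(self):
        vol = ImageVolume(np.zeros((3, 2, 2)), 1.0, 5.0)
        with pytest.raises(ConfigError):
            roi_stats(vol, np.ones((2, 2), bool), slice_policy=[])

    def test_empty_mask_errors(self):
        vol = ImageVolume(np.zeros((3, 2, 2)), 1.0, 5.0)
        with pytest.raises(ConfigError):
            roi_stats(vol, np.zeros((2, 2), bool))

    def test_central_fraction_selects_middle_slices(self):
        vox = np.zeros((5, 2, 2))
        vox[0] = vox[4] = 100.0  # end slices must be excluded
        vol = ImageVolume(vox, 1.0, 5.0)
        st = roi_stats(vol, np.ones((2, 2), bool), slice_policy=0.6)
        assert st.mean_hu == 0.0 and st.n_voxels == 12


class TestComputeCNR:
    def test_null_contrast(self):
        assert compute_cnr(ROIStats(50.0, 1.0, 30), ROIStats(50.0, 10.0, 30)) == 0.0

    def test_direct_arithmetic(self):
        assert compute_cnr(ROIStats(100.0, 5.0, 30), ROIStats(50.0, 10.0, 30)) == 5.0

    def test_sign_preserved_for_negative_contrast(self):
        assert compute_cnr(ROIStats(30.0, 5.0, 30), ROIStats(50.0, 10.0, 30)) == -2.0

    def test_zero_background_sd_errors(self):
        with pytest.raises(DegenerateInputError):
            compute_cnr(ROIStats(100.0, 5.0, 30), ROIStats(50.0, 0.0, 30))


class TestMeasurementProperties:
    def test_noise_free_cnr_with_nominal_sigma_is_exact(self, contrast, small_phantom):
        grid = GridSpec(pixel_spacing=2.5, n_slices=3)
        vol = generate_noise_free(small_phantom, acq(), contrast, grid)
        sigma_nominal = 13.0
        df = measure_image(vol, small_phantom, acq(), sd_override=sigma_nominal)
        kappa = contrast.kappa("DECT-VMI", 60.0)
        for _, row in df.iterrows():
            expected = kappa * row["concentration_mg_ml"] / sigma_nominal
            assert row["cnr"] == pytest.approx(expected, rel=1e-12)
            assert row["insert_mean_hu"] - row["background_mean_hu"] == pytest.approx(
                kappa * row["concentration_mg_ml"], rel=1e-12
            )

    def test_cnr_invariant_under_constant_offset(self, contrast, small_phantom, grid):
        noise = NoiseModel(recon_factors={"ir": 1.0})
        vol = generate_phantom_image(small_phantom, acq(), contrast, noise, grid, 21)
        shifted = ImageVolume(vol.voxels + 123.4, vol.pixel_spacing, vol.slice_thickness)
        a = measure_image(vol, small_phantom, acq())["cnr"].to_numpy()
        b = measure_image(shifted, small_phantom, acq())["cnr"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_simulated_cnr_matches_kappa_c_over_sigma(self, small_phantom):
        """Monte-Carlo mean CNR approaches kappa*c/sigma (kappa~26, c=10, sigma=13)."""
        grid = GridSpec(pixel_spacing=2.5, n_slices=3)
        noise = NoiseModel(sigma_ref=13.0, recon_factors={"ir": 1.0})
        contrast = ContrastModel()
        a = acq(energy=68.0)
        kappa = contrast.kappa("DECT-VMI", 68.0)
        sigma = noise.sigma(small_phantom.effective_diameter_cm, a.ctdi_vol, "ir")
        assert sigma == pytest.approx(13.0)
        vals = []
        for rep in range(30):
            vol = generate_phantom_image(
                small_phantom, a, contrast, noise, grid, child_seed(77, "mc", rep)
            )
            df = measure_image(vol, small_phantom, a)
            vals.append(df[df["concentration_mg_ml"] == 10.0]["cnr"].iloc[0])
        vals = np.asarray(vals)
        expected = kappa * 10.0 / sigma
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_cnr_scales_inversely_with_noise_sd(self, small_phantom, contrast):
        grid = GridSpec(pixel_spacing=2.5, n_slices=3)
        means = {}
        for s, sigma_ref in (("x1", 10.0), ("x2", 20.0)):
            noise = NoiseModel(sigma_ref=sigma_ref, recon_factors={"ir": 1.0})
            vals = [
                measure_image(
                    generate_phantom_image(
                        small_phantom, acq(), contrast, noise, grid, child_seed(5, s, rep)
                    ),
                    small_phantom,
                    acq(),
                )["cnr"].iloc[-1]
                for rep in range(25)
            ]
            means[s] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        ratio = means["x1"][0] / means["x2"][0]
        ratio_se = ratio * math.hypot(
            means["x1"][1] / means["x1"][0], means["x2"][1] / means["x2"][0]
        )
        assert abs(ratio - 2.0) < 3 * ratio_se
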