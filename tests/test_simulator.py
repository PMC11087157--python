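"""Synthetic phantom generator: exactness, noise calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from icmreduce import (
    AcquisitionSetting,
    ConfigError,
    ContrastModel,
    GridSpec,
    InsertSpec,
    NoiseModel,
    PhantomSpec,
    build_fixture_suite,
    child_seed,
    dect_phantom,
    generate_noise_free,
    generate_phantom_image,
    sect_phantom,
)
from icmreduce.simulate import body_mask, default_study_plan, insert_mask


def flat_kappa_table(kappa_at_40: float) -> pd.DataFrame:
    """Attenuation table engineered so kappa(40 keV) is exactly ``kappa_at_40``."""
    mu_w = 0.2
    return pd.DataFrame(
        {
            "energy_kev": [40.0, 150.0],
            "water_mu_rho_cm2_g": [mu_w, mu_w],
            "iodine_mu_rho_cm2_g": [mu_w * (1 + kappa_at_40), mu_w * (1 + kappa_at_40 / 2)],
        }
    )


def acq(energy=60.0, mode="DECT-VMI", ctdi=10.0, size="small_adult", recon="ir"):
    return AcquisitionSetting(mode, energy, "test", recon, ctdi, size)


class TestNoiseFreeStructure:
    def test_insert_voxels_exactly_background_plus_kappa_c(self, grid):
        contrast = ContrastModel(attenuation_table=flat_kappa_table(10.0))
        spec = dect_phantom("small_adult").with_concentrations([2.0, 5.0, 10.0, 15.0])
        vol = generate_noise_free(spec, acq(energy=40.0), contrast, grid)
        X, Y = vol.xy_grids()
        m = insert_mask(spec.inserts[0], X, Y)
        assert np.all(vol.voxels[:, m] == 20.0)  # 0 HU background + 10 * 2
        body = body_mask(spec, X, Y)
        for ins in spec.inserts[1:]:
            body &= ~insert_mask(ins, X, Y)
        assert np.all(vol.voxels[:, body & ~m] == 0.0)

    def test_air_outside_body(self, grid, small_phantom, contrast):
        vol = generate_noise_free(small_phantom, acq(), contrast, grid)
        X, Y = vol.xy_grids()
        outside = ~body_mask(small_phantom, X, Y)
        assert np.all(vol.voxels[:, outside] == -1000.0)

    def test_zero_concentration_insert_matches_background(self, grid, contrast, unit_noise):
        spec = dect_phantom("small_adult").with_concentrations([0.0, 5.0, 10.0, 15.0])
        vol = generate_phantom_image(spec, acq(), contrast, unit_noise, grid, 7)
        X, Y = vol.xy_grids()
        m = insert_mask(spec.inserts[0], X, Y)
        vox = vol.voxels[:, m].ravel()
        se = vox.std(ddof=1) / np.sqrt(vox.size)
        assert abs(vox.mean() - spec.background_hu) < 3 * se


class TestNoiseCalibration:
    def sample_background_sd(self, noise, grid, seed=3, ctdi=10.0):
        spec = dect_phantom("small_adult")
        vol = generate_phantom_image(spec, acq(ctdi=ctdi), ContrastModel(), noise, grid, seed)
        X, Y = vol.xy_grids()
        bg = body_mask(spec, X, Y)
        for ins in spec.inserts:
            bg &= (X - ins.center_xy[0]) ** 2 + (Y - ins.center_xy[1]) ** 2 > (
                ins.diameter / 2 + 4
            ) ** 2
        sample = vol.voxels[:, bg].ravel()
        assert sample.size >= 10_000
        return float(np.std(sample, ddof=1))

    def test_realized_sd_within_5pct_of_nominal(self, grid):
        noise = NoiseModel(sigma_ref=12.0, recon_factors={"ir": 1.0})
        sd = self.sample_background_sd(noise, grid)
        assert sd == pytest.approx(12.0, rel=0.05)

    def test_doubling_dose_scales_sd_by_sqrt2(self, grid):
        noise = NoiseModel(sigma_ref=12.0, recon_factors={"ir": 1.0})
        sd1 = self.sample_background_sd(noise, grid, seed=11, ctdi=10.0)
        sd2 = self.sample_background_sd(noise, grid, seed=12, ctdi=20.0)
        assert sd1 / sd2 == pytest.approx(np.sqrt(2.0), rel=0.03)

    def test_sd_increases_with_phantom_size_at_fixed_dose(self, grid, contrast):
        noise = NoiseModel(recon_factors={"ir": 1.0})
        sds = []
        for size in ("small_adult", "medium_adult", "large_adult", "xl_adult"):
            spec = dect_phantom(size)
            vol = generate_phantom_image(
                spec, acq(size=size), contrast, noise, grid, 5
            )
            X, Y = vol.xy_grids()
            bg = body_mask(spec, X, Y)
            for ins in spec.inserts:
                bg &= (X - ins.center_xy[0]) ** 2 + (Y - ins.center_xy[1]) ** 2 > (
                    ins.diameter / 2 + 4
                ) ** 2
            sds.append(float(np.std(vol.voxels[:, bg], ddof=1)))
        assert all(a < b for a, b in zip(sds, sds[1:]))


class TestDeterminism:
    def test_identical_inputs_bit_identical_volumes(self, grid, contrast, unit_noise, small_phantom):
        v1 = generate_phantom_image(small_phantom, acq(), contrast, unit_noise, grid, 42)
        v2 = generate_phantom_image(small_phantom, acq(), contrast, unit_noise, grid, 42)
        assert np.array_equal(v1.voxels, v2.voxels)

    def test_child_seed_depends_only_on_labels(self):
        a = child_seed(9, "scanner", "SECT", 120, "small_adult", "ir")
        b = child_seed(9, "scanner", "SECT", 120, "small_adult", "ir")
        c = child_seed(9, "scanner", "SECT", 100, "small_adult", "ir")
        assert a == b != c
        assert 0 <= a < 2**31


class TestGeometryErrors:
    def test_insert_outside_body_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(
                semi_axes=(50.0, 50.0),
                background_hu=0.0,
                inserts=(InsertSpec((45.0, 0.0), 20.0, 5.0),),
                z_length=100.0,
            )

    def test_overlapping_inserts_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(
                semi_axes=(80.0, 80.0),
                background_hu=0.0,
                inserts=(
                    InsertSpec((0.0, 0.0), 20.0, 5.0),
                    InsertSpec((15.0, 0.0), 20.0, 10.0),
                ),
                z_length=100.0,
            )

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ConfigError):
            GridSpec(pixel_spacing=0.0)

    def test_grid_too_small_rejected(self, contrast, unit_noise):
        tiny = GridSpec(pixel_spacing=2.5, n_slices=2, shape_xy=(20, 20))
        with pytest.raises(ConfigError):
            generate_phantom_image(
                dect_phantom("small_adult"), acq(), contrast, unit_noise, tiny, 0
            )

    def test_inconsistent_effective_diameter_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(
                semi_axes=(100.0, 100.0),
                background_hu=0.0,
                inserts=(),
                z_length=100.0,
                effective_diameter_cm=25.0,  # true value is 20.0
            )


class TestFixtureSuite:
    def test_manifest_rows_equal_files_written(self, tmp_path, grid):
        plan = [
            (dect_phantom("small_adult"), acq(energy=e))
            for e in (50.0, 60.0)
        ] + [(sect_phantom("newborn"), acq(mode="SECT", energy=120, size="newborn", recon="sbir", ctdi=1.5))]
        manifest = build_fixture_suite(3, tmp_path, plan=plan, grid=grid)
        files = sorted(tmp_path.glob("*.npz"))
        assert len(manifest) == len(plan) == len(files)
        assert (tmp_path / "manifest.csv").exists()

    def test_default_plan_concentration_sets(self):
        plan = default_study_plan()
        sect = [p for p, a in plan if a.mode == "SECT" and a.scanner_label.startswith("sect")]
        dect = [p for p, a in plan if a.mode == "DECT-VMI"]
        assert {i.concentration for i in sect[0].inserts} == {2.0, 5.0, 10.0, 15.0, 20.0}
        assert {i.concentration for i in dect[0].inserts} == {2.0, 5.0, 10.0, 15.0}

    def test_default_plan_covers_all_sizes_and_skips_70kv_large_bodies(self):
        plan = default_study_plan()
        sizes = {p.size_label for p, _ in plan}
        assert sizes == {
            "newborn", "five_yo", "fifteen_yo", "medium_adult",
            "small_adult", "large_adult", "xl_adult",
        }
        kv70 = {a.size_label for _, a in plan if a.mode == "SECT" and a.energy == 70}
        assert kv70 == {"newborn", "five_yo"}
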