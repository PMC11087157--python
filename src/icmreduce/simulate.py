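"""Synthetic phantom CT image generation.

Generates HU volumes with exactly the statistical structure the downstream
analysis assumes: air (-1000 HU) outside the body, a constant background HU
inside it, background + kappa(E) * concentration inside each iodine insert,
and i.i.d. additive Gaussian noise (SD from :class:`~icmreduce.phantom.NoiseModel`)
on every body voxel.  Voxels are classified by their centre point; there is
no partial-volume weighting because measurement ROIs erode insert edges
anyway.

Randomness: one top-level seed; each volume draws from a child generator
seeded by a stable (sha256) hash of its stratum labels plus the top seed,
so adding a volume to a suite never perturbs the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attenuation import ContrastModel
from .errors import ConfigError
from .phantom import (
    DECT_SIZES_CM,
    HU_AIR,
    SECT_SIZES_CM,
    AcquisitionSetting,
    NoiseModel,
    PhantomSpec,
    dect_phantom,
    sect_phantom,
)
from .volume import ImageVolume


def child_seed(seed: int, *labels) -> int:
    """Deterministic per-volume seed from the top-level seed and stratum labels."""
    key = "|".join([str(int(seed))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid for generated volumes."""

    pixel_spacing: float = 2.0  # mm
    n_slices: int = 5
    slice_thickness: float = 5.0  # mm
    margin: float = 10.0  # mm of air around the body
    shape_xy: tuple[int, int] | None = None  # (ny, nx); derived if None

    def __post_init__(self):
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ConfigError("grid spacing must be positive")
        if self.n_slices < 1:
            raise ConfigError("grid needs at least one slice")

    def shape_for(self, spec: PhantomSpec) -> tuple[int, int, int]:
        if self.shape_xy is not None:
            ny, nx = self.shape_xy
        else:
            a, b = spec.semi_axes
            nx = int(math.ceil(2 * (a + self.margin) / self.pixel_spacing)) + 1
            ny = int(math.ceil(2 * (b + self.margin) / self.pixel_spacing)) + 1
        return (self.n_slices, ny, nx)


def body_mask(spec: PhantomSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    a, b = spec.semi_axes
    return (X / a) ** 2 + (Y / b) ** 2 <= 1.0


def insert_mask(ins, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    cx, cy = ins.center_xy
    return (X - cx) ** 2 + (Y - cy) ** 2 <= (ins.diameter / 2.0) ** 2


def generate_phantom_image(
    spec: PhantomSpec,
    acq: AcquisitionSetting,
    contrast: ContrastModel,
    noise: NoiseModel,
    grid: GridSpec,
    seed: int,
) -> ImageVolume:
    """Simulate one phantom acquisition.

    Deterministic for identical inputs.  The noise SD applied is
    ``noise.sigma(spec.effective_diameter_cm, acq.ctdi_vol, acq.recon_label)``;
    a zero-variance model (``sigma_ref`` cannot be zero, but see
    ``generate_noise_free``) is supported through ``sigma=0`` internally.
    """
    sigma = noise.sigma(spec.effective_diameter_cm, acq.ctdi_vol, acq.recon_label)
    return _generate(spec, acq, contrast, sigma, grid, seed)


def generate_noise_free(
    spec: PhantomSpec,
    acq: AcquisitionSetting,
    contrast: ContrastModel,
    grid: GridSpec,
) -> ImageVolume:
    """The simulator's noiseless expectation image (for oracle checks)."""
    return _generate(spec, acq, contrast, 0.0, grid, seed=0)


def _generate(spec, acq, contrast, sigma, grid: GridSpec, seed: int) -> ImageVolume:
    nz, ny, nx = grid.shape_for(spec)
    half_x = (nx - 1) / 2.0 * grid.pixel_spacing
    half_y = (ny - 1) / 2.0 * grid.pixel_spacing
    a, b = spec.semi_axes
    if a > half_x or b > half_y:
        raise ConfigError(
            f"grid ({ny}x{nx} at {grid.pixel_spacing} mm) too small for body semi-axes {spec.semi_axes}"
        )
    x = (np.arange(nx) - (nx - 1) / 2.0) * grid.pixel_spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * grid.pixel_spacing
    X, Y = np.meshgrid(x, y)

    body = body_mask(spec, X, Y)
    slice_hu = np.full((ny, nx), HU_AIR)
    slice_hu[body] = spec.background_hu
    kappa = contrast.kappa(acq.mode, acq.energy)
    for ins in spec.inserts:
        m = insert_mask(ins, X, Y)
        slice_hu[m] = spec.background_hu + kappa * ins.concentration

    voxels = np.repeat(slice_hu[None, :, :], nz, axis=0)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        body3d = np.repeat(body[None, :, :], nz, axis=0)
        voxels[body3d] += rng.normal(0.0, sigma, int(body3d.sum()))
    return ImageVolume(voxels, grid.pixel_spacing, grid.slice_thickness)


# --------------------------------------------------------------- study plan

SECT_CTDI_MGY = {"newborn": 1.5, "five_yo": 3.0, "fifteen_yo": 6.0, "medium_adult": 10.0}
DECT_CTDI_MGY = {"small_adult": 10.0, "medium_adult": 18.0, "large_adult": 26.0, "xl_adult": 35.0}

#: Low-kV single-energy study arms: scanner -> (kV stations, recon labels).
SECT_STUDY = {
    "sect_a": ((70, 80, 100, 120, 140), ("sbir", "dlr")),
    "sect_b": ((80, 100, 120, 135), ("sbir", "dlr")),
}
#: 70 kV tube output cannot hold noise constant for the two largest bodies,
#: so those arms are absent from the plan (mirrors the physical study design).
SECT_70KV_EXCLUDED_SIZES = ("fifteen_yo", "medium_adult")

#: DECT study arms: scanner -> VMI energies (keV); each scanner also
#: acquires SECT 100 and 120 kV baselines.
DECT_STUDY = {
    "fast_kv": (40, 50, 60, 68),
    "dual_source": (40, 50, 60, 70, 80),
    "dual_layer": (40, 50, 60, 70),
}
DECT_BASELINE_KV = (100, 120)
DECT_RECON = "ir"


def default_study_plan(
    sect_sizes=None, dect_sizes=None, sect_background_hu: float = 35.0,
    dect_background_hu: float = 0.0,
) -> list[tuple[PhantomSpec, AcquisitionSetting]]:
    """Every (phantom, acquisition) pair of the emulated two-part study."""
    plan: list[tuple[PhantomSpec, AcquisitionSetting]] = []
    for size in (sect_sizes if sect_sizes is not None else SECT_SIZES_CM):
        spec = sect_phantom(size, background_hu=sect_background_hu)
        for scanner, (kvs, recons) in SECT_STUDY.items():
            for kv in kvs:
                if scanner == "sect_a" and kv == 70 and size in SECT_70KV_EXCLUDED_SIZES:
                    continue
                for recon in recons:
                    plan.append(
                        (
                            spec,
                            AcquisitionSetting(
                                "SECT", kv, scanner, recon, SECT_CTDI_MGY[size], size
                            ),
                        )
                    )
    for size in (dect_sizes if dect_sizes is not None else DECT_SIZES_CM):
        spec = dect_phantom(size, background_hu=dect_background_hu)
        for scanner, kevs in DECT_STUDY.items():
            settings = [("SECT", kv) for kv in DECT_BASELINE_KV]
            settings += [("DECT-VMI", kev) for kev in kevs]
            for mode, energy in settings:
                plan.append(
                    (
                        spec,
                        AcquisitionSetting(
                            mode, energy, scanner, DECT_RECON, DECT_CTDI_MGY[size], size
                        ),
                    )
                )
    return plan


MANIFEST_COLUMNS = [
    "file",
    "scanner_label",
    "mode",
    "energy",
    "size_label",
    "recon_label",
    "ctdi_vol",
    "effective_diameter_cm",
    "background_hu",
    "concentrations_mg_ml",
    "child_seed",
]


def build_fixture_suite(
    seed: int,
    out_dir,
    plan: list[tuple[PhantomSpec, AcquisitionSetting]] | None = None,
    contrast: ContrastModel | None = None,
    noise: NoiseModel | None = None,
    grid: GridSpec | None = None,
    container: str = "npz",
) -> pd.DataFrame:
    """Generate a suite of phantom volumes and a manifest CSV.

    One volume per (phantom, acquisition) entry of ``plan`` (default: the
    full two-part study).  Returns the manifest, which is also written to
    ``out_dir/manifest.csv``; the manifest row count always equals the
    number of volumes written.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = default_study_plan() if plan is None else plan
    contrast = contrast or ContrastModel()
    noise = noise or NoiseModel()
    grid = grid or GridSpec()
    if container not in ("npz", "dicom"):
        raise ConfigError(f"unknown container {container!r}; use 'npz' or 'dicom'")

    rows = []
    for spec, acq in plan:
        cs = child_seed(seed, *acq.stratum)
        vol = generate_phantom_image(spec, acq, contrast, noise, grid, cs)
        stem = "{}_{}_{:g}_{}_{}".format(
            acq.scanner_label, acq.mode.lower().replace("-", ""), acq.energy,
            acq.size_label, acq.recon_label,
        )
        meta = {
            "scanner_label": acq.scanner_label,
            "mode": acq.mode,
            "energy": acq.energy,
            "size_label": acq.size_label,
            "recon_label": acq.recon_label,
            "ctdi_vol": acq.ctdi_vol,
            "child_seed": cs,
        }
        if container == "npz":
            vol.save_npz(out_dir / stem, metadata=meta)
            fname = stem + ".npz"
        else:
            vol.save_dicom_series(out_dir / stem, series_description=stem, entropy=str(cs))
            fname = stem
        rows.append(
            {
                "file": fname,
                "scanner_label": acq.scanner_label,
                "mode": acq.mode,
                "energy": acq.energy,
                "size_label": acq.size_label,
                "recon_label": acq.recon_label,
                "ctdi_vol": acq.ctdi_vol,
                "effective_diameter_cm": spec.effective_diameter_cm,
                "background_hu": spec.background_hu,
                "concentrations_mg_ml": ";".join(
                    f"{i.concentration:g}" for i in spec.inserts
                ),
                "child_seed": cs,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
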