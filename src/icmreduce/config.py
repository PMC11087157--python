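"""YAML run configuration for the end-to-end pipeline.

A run config has six required blocks — ``phantom``, ``acquisition``,
``contrast_model``, ``noise_model``, ``grid``, ``seed`` — plus optional
``measure`` and ``plan`` blocks mirroring those stages' keyword arguments.
See ``data/mini_config.yaml`` for a small working example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .attenuation import DEFAULT_KV_TO_KEV, ContrastModel
from .errors import ConfigError
from .io import config_hash
from .phantom import AcquisitionSetting, NoiseModel, PhantomSpec, dect_phantom, sect_phantom
from .simulate import GridSpec

REQUIRED_BLOCKS = ("phantom", "acquisition", "contrast_model", "noise_model", "grid", "seed")


@dataclass
class RunConfig:
    """Parsed, validated pipeline configuration."""

    raw: dict
    seed: int
    phantoms: list[PhantomSpec]
    acquisitions: dict[str, list]  # size_label -> list of AcquisitionSetting
    contrast: ContrastModel
    noise: NoiseModel
    grid: GridSpec
    replicates: int = 1
    measure_opts: dict = field(default_factory=dict)
    plan_opts: dict = field(default_factory=dict)

    @property
    def sha(self) -> str:
        return config_hash(self.raw)

    def plan_entries(self) -> list[tuple[PhantomSpec, AcquisitionSetting]]:
        entries = []
        for spec in self.phantoms:
            for acq in self.acquisitions[spec.size_label]:
                entries.append((spec, acq))
        return entries


def mini_config_path() -> Path:
    """Path to the packaged miniature demo configuration."""
    return Path(str(resources.files("icmreduce.data") / "mini_config.yaml"))


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    for block in REQUIRED_BLOCKS:
        if block not in raw:
            raise ConfigError(f"config missing required block {block!r}")

    seed = int(raw["seed"])

    cm_block = raw["contrast_model"] or {}
    kv_map = {int(k): float(v) for k, v in (cm_block.get("kv_to_kev") or DEFAULT_KV_TO_KEV).items()}
    contrast = ContrastModel(kv_to_kev=kv_map)

    nm = raw["noise_model"] or {}
    noise = NoiseModel(
        sigma_ref=float(nm.get("sigma_ref_hu", 10.0)),
        d_ref=float(nm.get("d_ref_cm", 20.0)),
        ctdi_ref=float(nm.get("ctdi_ref_mgy", 10.0)),
        size_coeff=float(nm.get("size_coeff_per_cm", 0.09)),
        recon_factors={str(k): float(v) for k, v in (nm.get("recon_factors") or {"sbir": 1.0, "dlr": 0.6, "ir": 0.9}).items()},
    )

    g = raw["grid"] or {}
    grid = GridSpec(
        pixel_spacing=float(g.get("pixel_spacing_mm", 2.0)),
        n_slices=int(g.get("n_slices", 5)),
        slice_thickness=float(g.get("slice_thickness_mm", 5.0)),
    )

    ph = raw["phantom"] or {}
    study = str(ph.get("study", "dect")).lower()
    if study not in ("sect", "dect"):
        raise ConfigError(f"phantom.study must be 'sect' or 'dect', got {study!r}")
    factory = sect_phantom if study == "sect" else dect_phantom
    default_bg = 35.0 if study == "sect" else 0.0
    background_hu = float(ph.get("background_hu", default_bg))
    sizes = ph.get("sizes")
    if not sizes:
        raise ConfigError("phantom block must list 'sizes'")
    phantoms = [factory(size, background_hu=background_hu) for size in sizes]

    acq_block = raw["acquisition"] or {}
    scanner = str(acq_block.get("scanner_label", "scanner"))
    recon = str(acq_block.get("recon_label", "ir"))
    ctdi_by_size = acq_block.get("ctdi_by_size") or {}
    techniques = [acq_block.get("baseline")] + list(acq_block.get("targets") or [])
    techniques = [t for t in techniques if t]
    if not techniques:
        raise ConfigError("acquisition block needs a 'baseline' and/or 'targets'")
    acquisitions: dict[str, list] = {}
    for spec in phantoms:
        if spec.size_label not in ctdi_by_size:
            raise ConfigError(f"acquisition.ctdi_by_size missing entry for {spec.size_label!r}")
        acquisitions[spec.size_label] = [
            AcquisitionSetting(
                mode=str(t["mode"]),
                energy=float(t["energy"]),
                scanner_label=scanner,
                recon_label=recon,
                ctdi_vol=float(ctdi_by_size[spec.size_label]),
                size_label=spec.size_label,
            )
            for t in techniques
        ]

    return RunConfig(
        raw=raw,
        seed=seed,
        phantoms=phantoms,
        acquisitions=acquisitions,
        contrast=contrast,
        noise=noise,
        grid=grid,
        replicates=int(raw.get("replicates", 1)),
        measure_opts=dict(raw.get("measure") or {}),
        plan_opts=dict(raw.get("plan") or {}),
    )
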