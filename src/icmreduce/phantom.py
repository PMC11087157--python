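"""Phantom geometry, acquisition metadata, and the simulator noise model.

Physical coordinates are millimetres with the origin at the phantom centre;
``effective diameter`` is the equivalent circular diameter 2*sqrt(a*b) of an
elliptical cross-section with semi-axes a, b, the standard size surrogate
for CT protocol strata.

Two phantom families mirror the study designs this package emulates:

* a paediatric-to-adult abdomen series (effective diameters 9.7, 15.9,
  21.1, 28.5 cm) carrying five 13.1 mm iodine rods at 2-20 mg/mL, used for
  the low-kV single-energy comparisons, and
* an adult multi-energy series (20, 29.5, 34.6, 39.7 cm) carrying four
  28.5 mm iodine inserts at 2-15 mg/mL, used for the DECT-VMI comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError

HU_AIR = -1000.0

SECT_TUBE_POTENTIALS = (70, 80, 100, 120, 135, 140)
VMI_KEV_MIN, VMI_KEV_MAX = 40.0, 140.0

SECT_SIZES_CM: dict[str, float] = {
    "newborn": 9.7,
    "five_yo": 15.9,
    "fifteen_yo": 21.1,
    "medium_adult": 28.5,
}
DECT_SIZES_CM: dict[str, float] = {
    "small_adult": 20.0,
    "medium_adult": 29.5,
    "large_adult": 34.6,
    "xl_adult": 39.7,
}
SECT_CONCENTRATIONS = (2.0, 5.0, 10.0, 15.0, 20.0)
DECT_CONCENTRATIONS = (2.0, 5.0, 10.0, 15.0)

SECT_ROD_DIAMETER_MM = 13.1
DECT_INSERT_DIAMETER_MM = 28.5


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical iodine insert (full z extent of the phantom)."""

    center_xy: tuple[float, float]  # mm, phantom-centre origin
    diameter: float  # mm
    concentration: float  # mg/mL iodine

    def __post_init__(self):
        if self.diameter <= 0:
            raise ConfigError(f"insert diameter must be > 0, got {self.diameter}")
        if self.concentration < 0:
            raise ConfigError(f"insert concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class PhantomSpec:
    """A water-equivalent elliptical body carrying iodine inserts."""

    semi_axes: tuple[float, float]  # (a, b) mm; circle when a == b
    background_hu: float
    inserts: tuple[InsertSpec, ...]
    z_length: float  # mm
    size_label: str = ""
    effective_diameter_cm: float | None = None

    def __post_init__(self):
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ConfigError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.z_length <= 0:
            raise ConfigError("z_length must be positive")
        derived = 2.0 * math.sqrt(a * b) / 10.0
        if self.effective_diameter_cm is None:
            object.__setattr__(self, "effective_diameter_cm", derived)
        elif abs(self.effective_diameter_cm - derived) > 0.1:
            raise ConfigError(
                f"effective_diameter_cm={self.effective_diameter_cm} inconsistent with "
                f"semi-axes (derived {derived:.2f} cm)"
            )
        object.__setattr__(self, "inserts", tuple(self.inserts))
        for ins in self.inserts:
            if not self.contains_disk(ins.center_xy, ins.diameter / 2.0):
                raise ConfigError(
                    f"insert at {ins.center_xy} (d={ins.diameter} mm) extends outside "
                    f"the phantom body (semi-axes {self.semi_axes})"
                )
        for i, p in enumerate(self.inserts):
            for q in self.inserts[i + 1:]:
                d = math.hypot(p.center_xy[0] - q.center_xy[0], p.center_xy[1] - q.center_xy[1])
                if d < (p.diameter + q.diameter) / 2.0:
                    raise ConfigError(
                        f"inserts at {p.center_xy} and {q.center_xy} overlap"
                    )

    def contains_disk(self, center_xy, radius: float, n_boundary: int = 64) -> bool:
        """True if the disk lies entirely inside the elliptical body."""
        a, b = self.semi_axes
        phi = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
        px = center_xy[0] + radius * np.cos(phi)
        py = center_xy[1] + radius * np.sin(phi)
        return bool(np.all((px / a) ** 2 + (py / b) ** 2 <= 1.0 + 1e-9))

    def with_concentrations(self, concentrations) -> "PhantomSpec":
        """Copy of this phantom with insert concentrations replaced in order."""
        conc = list(concentrations)
        if len(conc) != len(self.inserts):
            raise ConfigError(
                f"expected {len(self.inserts)} concentrations, got {len(conc)}"
            )
        new = tuple(replace(ins, concentration=float(c)) for ins, c in zip(self.inserts, conc))
        return replace(self, inserts=new)


@dataclass(frozen=True)
class AcquisitionSetting:
    """Stratum metadata for one acquisition technique."""

    mode: str  # "SECT" or "DECT-VMI"
    energy: float  # kV for SECT, keV for DECT-VMI
    scanner_label: str
    recon_label: str
    ctdi_vol: float  # mGy
    size_label: str = ""

    def __post_init__(self):
        mode = self.mode.upper()
        if mode not in ("SECT", "DECT-VMI"):
            raise ConfigError(f"mode must be 'SECT' or 'DECT-VMI', got {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if mode == "SECT":
            if int(self.energy) not in SECT_TUBE_POTENTIALS:
                raise ConfigError(
                    f"SECT tube potential {self.energy} kV not among {SECT_TUBE_POTENTIALS}"
                )
        else:
            if not (VMI_KEV_MIN <= self.energy <= VMI_KEV_MAX):
                raise ConfigError(
                    f"VMI energy {self.energy} keV outside [{VMI_KEV_MIN}, {VMI_KEV_MAX}]"
                )
        if self.ctdi_vol <= 0:
            raise ConfigError("ctdi_vol must be positive")

    @property
    def stratum(self) -> tuple:
        return (self.scanner_label, self.mode, self.energy, self.size_label, self.recon_label)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian image-noise magnitude as a function of size, dose, recon.

    sigma(d, ctdi, recon) = sigma_ref * exp(size_coeff * (d - d_ref))
                                      * sqrt(ctdi_ref / ctdi) * recon_factor

    The exponential size term reflects photon starvation through thicker
    water paths (noise roughly doubles every ~8 cm of water at abdominal
    energies, hence the default 0.09/cm), the inverse-square-root dose term
    is quantum-limited noise, and per-reconstruction multiplicative factors
    stand in for iterative / deep-learning noise reduction.  All constants
    are configuration, not measured truth.
    """

    sigma_ref: float = 10.0  # HU at (d_ref, ctdi_ref), unit recon factor
    d_ref: float = 20.0  # cm effective diameter
    ctdi_ref: float = 10.0  # mGy
    size_coeff: float = 0.09  # per cm
    recon_factors: dict[str, float] = field(
        default_factory=lambda: {"sbir": 1.0, "dlr": 0.6, "ir": 0.9}
    )

    def __post_init__(self):
        if self.sigma_ref <= 0 or self.ctdi_ref <= 0 or self.d_ref <= 0:
            raise ConfigError("noise model reference values must be positive")
        for label, f in self.recon_factors.items():
            if f <= 0:
                raise ConfigError(f"recon factor for {label!r} must be positive")

    def sigma(self, effective_diameter_cm: float, ctdi_vol: float, recon_label: str = "") -> float:
        """Noise SD in HU for a (size, dose, reconstruction) stratum."""
        if ctdi_vol <= 0:
            raise ConfigError("ctdi_vol must be positive")
        factor = self.recon_factors.get(recon_label, 1.0)
        return (
            self.sigma_ref
            * math.exp(self.size_coeff * (effective_diameter_cm - self.d_ref))
            * math.sqrt(self.ctdi_ref / ctdi_vol)
            * factor
        )


def _ring_positions(a: float, b: float, ring_fraction: float, angles_deg) -> list[tuple[float, float]]:
    out = []
    for ang in angles_deg:
        t = math.radians(ang)
        out.append((ring_fraction * a * math.cos(t), ring_fraction * b * math.sin(t)))
    return out


def sect_phantom(size_label: str, background_hu: float = 35.0) -> PhantomSpec:
    """Paediatric/adult abdomen phantom with five 13.1 mm rods at 2-20 mg/mL.

    Elliptical body (aspect ratio 1.25); four rods on a peripheral ring
    (2, 5, 15, 20 mg/mL) plus one at the centre (10 mg/mL).  Background is a
    soft-tissue-equivalent 35 HU by default.
    """
    try:
        eff = SECT_SIZES_CM[size_label]
    except KeyError:
        raise ConfigError(
            f"unknown SECT phantom size {size_label!r}; options: {sorted(SECT_SIZES_CM)}"
        ) from None
    aspect = 1.25
    ab = (5.0 * eff) ** 2  # mm^2
    a = math.sqrt(ab * aspect)
    b = a / aspect
    centers = _ring_positions(a, b, 0.6, (45, 135, 225, 315))
    conc = (2.0, 5.0, 15.0, 20.0)
    inserts = [
        InsertSpec(c, SECT_ROD_DIAMETER_MM, k) for c, k in zip(centers, conc)
    ] + [InsertSpec((0.0, 0.0), SECT_ROD_DIAMETER_MM, 10.0)]
    return PhantomSpec(
        semi_axes=(a, b),
        background_hu=background_hu,
        inserts=tuple(inserts),
        z_length=150.0,
        size_label=size_label,
    )


def dect_phantom(size_label: str, background_hu: float = 0.0) -> PhantomSpec:
    """Adult multi-energy phantom with four 28.5 mm inserts at 2-15 mg/mL.

    A 20 cm solid-water core houses the inserts on a 60 mm ring; larger
    sizes are the same core enclosed in elliptical annuli (modelled here as
    a single water-equivalent ellipse of matching effective diameter).
    """
    try:
        eff = DECT_SIZES_CM[size_label]
    except KeyError:
        raise ConfigError(
            f"unknown DECT phantom size {size_label!r}; options: {sorted(DECT_SIZES_CM)}"
        ) from None
    if size_label == "small_adult":
        a = b = 100.0
    else:
        aspect = 1.35
        ab = (5.0 * eff) ** 2
        a = math.sqrt(ab * aspect)
        b = a / aspect
    ring_r = 60.0
    centers = [
        (ring_r * math.cos(math.radians(t)), ring_r * math.sin(math.radians(t)))
        for t in (45, 135, 225, 315)
    ]
    inserts = tuple(
        InsertSpec(c, DECT_INSERT_DIAMETER_MM, k)
        for c, k in zip(centers, DECT_CONCENTRATIONS)
    )
    return PhantomSpec(
        semi_axes=(a, b),
        background_hu=background_hu,
        inserts=inserts,
        z_length=165.0,
        size_label=size_label,
    )
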