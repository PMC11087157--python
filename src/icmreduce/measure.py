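"""ROI placement and contrast-to-noise measurement.

CNR definition used throughout the package:

    CNR = (mean_insert - mean_background) / SD_background

with the SD taken from pooled background ROIs (never the insert ROI, whose
texture would conflate contrast with noise), using the sample (n-1)
estimator.  The sign is preserved so a mis-specified negative-contrast
insert is visible in QA output.

ROI layout: one circular ROI per insert, concentric with it and eroded to
``roi_fraction`` (default 0.7) of the insert diameter to exclude edge
partial-volume pixels; four background ROIs of the same area placed at
insert-free positions on the insert ring, pooled into a single background
sample.  Two placement modes exist: ``geometry`` (from the phantom spec)
and ``auto`` (threshold + connected components, matched to the spec by
nearest centre); on noise-free images the two agree to within one pixel.

Statistics pool voxels across the central fraction of slices (default 60%)
before computing mean/SD, since end slices of physical contrast rods risk
cone-beam and edge effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, DetectionError
from .phantom import AcquisitionSetting, PhantomSpec
from .simulate import body_mask
from .volume import ImageVolume

STRATUM_COLUMNS = ["scanner_label", "mode", "energy", "size_label", "recon_label"]

MIN_ROI_VOXELS = 25


@dataclass(frozen=True)
class ROIStats:
    """Summary statistics of one ROI."""

    mean_hu: float
    sd_hu: float
    n_voxels: int
    label: str = ""


@dataclass(frozen=True)
class CNRMeasurement:
    """One (stratum, concentration) -> CNR observation."""

    stratum: tuple
    concentration: float
    cnr: float
    insert_stats: ROIStats
    background_stats: ROIStats


@dataclass
class ROILayout:
    """Pixel masks (2-D, applied across slices) for one phantom image."""

    insert_masks: list[np.ndarray]
    insert_centers: list[tuple[float, float]]  # mm
    background_masks: list[np.ndarray]

    @property
    def background_mask(self) -> np.ndarray:
        pooled = np.zeros_like(self.background_masks[0], dtype=bool)
        for m in self.background_masks:
            pooled |= m
        return pooled


def _disk_mask(X, Y, center, radius):
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2


def _auto_centers(image: ImageVolume, spec: PhantomSpec, threshold_hu: float):
    """Detect high-HU disks on the slice-averaged image; return centres (mm)."""
    from skimage import filters
    from skimage import measure as skmeasure

    mean_slice = image.voxels.mean(axis=0)
    smoothed = filters.gaussian(mean_slice, sigma=1.5, preserve_range=True)
    X, Y = image.xy_grids()
    body = body_mask(spec, X, Y)
    high = (smoothed > spec.background_hu + threshold_hu) & body
    labels = skmeasure.label(high)
    min_area = 0.3 * math.pi * (min(i.diameter for i in spec.inserts) / 2.0) ** 2 / image.pixel_spacing**2
    centers = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_area:
            continue
        cy, cx = region.centroid  # row, col
        ny, nx = mean_slice.shape
        centers.append(
            (
                (cx - (nx - 1) / 2.0) * image.pixel_spacing,
                (cy - (ny - 1) / 2.0) * image.pixel_spacing,
            )
        )
    return centers


def _background_positions(spec: PhantomSpec, roi_radius: float, n_background: int, margin: float = 2.0):
    """Search insert-free positions for the background ROIs.

    Candidates live on the ring through the insert centres (falling back to
    half the minor semi-axis if all inserts are central); the offset of an
    evenly spaced set of ``n_background`` angles is chosen to maximise the
    worst-case clearance from the inserts.
    """
    radii = [math.hypot(*ins.center_xy) for ins in spec.inserts]
    ring = [r for r in radii if r > 1e-9]
    ring_r = float(np.mean(ring)) if ring else 0.5 * min(spec.semi_axes)

    def clearance(pos):
        c = min(
            math.hypot(pos[0] - ins.center_xy[0], pos[1] - ins.center_xy[1])
            - ins.diameter / 2.0
            - roi_radius
            for ins in spec.inserts
        )
        if not spec.contains_disk(pos, roi_radius):
            return -math.inf
        return c

    best_offset, best_score = None, -math.inf
    for offset in np.arange(0.0, 360.0 / n_background, 2.0):
        angles = offset + np.arange(n_background) * 360.0 / n_background
        positions = [
            (ring_r * math.cos(math.radians(t)), ring_r * math.sin(math.radians(t)))
            for t in angles
        ]
        score = min(clearance(p) for p in positions)
        if score > best_score:
            best_offset, best_score = positions, score
    if best_offset is None or best_score < margin:
        raise ConfigError(
            "could not place background ROIs clear of the inserts; "
            "supply explicit background_offsets"
        )
    return best_offset


def locate_rois(
    image: ImageVolume,
    spec: PhantomSpec,
    roi_fraction: float = 0.7,
    mode: str = "geometry",
    background_offsets=None,
    n_background: int = 4,
    detect_threshold_hu: float = 25.0,
) -> ROILayout:
    """Build insert and background ROI masks for a phantom image.

    ``mode='geometry'`` centres each ROI on the spec'd insert position;
    ``mode='auto'`` detects insert disks by thresholding and matches them to
    the spec by nearest centre (raising :class:`DetectionError`, naming the
    insert, if one is missed).  ``background_offsets`` may give explicit
    (x, y) mm positions; overlap with an insert raises :class:`ConfigError`.
    """
    if not (0.0 < roi_fraction <= 0.9):
        raise ConfigError(f"roi_fraction must be in (0, 0.9], got {roi_fraction}")
    if mode not in ("geometry", "auto"):
        raise ConfigError(f"unknown ROI mode {mode!r}")
    X, Y = image.xy_grids()

    centers = [ins.center_xy for ins in spec.inserts]
    if mode == "auto":
        detected = _auto_centers(image, spec, detect_threshold_hu)
        matched = []
        for i, ins in enumerate(spec.inserts):
            cands = [
                d
                for d in detected
                if math.hypot(d[0] - ins.center_xy[0], d[1] - ins.center_xy[1])
                <= ins.diameter / 2.0
            ]
            if not cands:
                raise DetectionError(
                    f"auto ROI detection found no component for insert {i} "
                    f"(c={ins.concentration} mg/mL at {ins.center_xy})"
                )
            matched.append(
                min(
                    cands,
                    key=lambda d: math.hypot(
                        d[0] - ins.center_xy[0], d[1] - ins.center_xy[1]
                    ),
                )
            )
        centers = matched

    insert_masks = []
    for ins, c in zip(spec.inserts, centers):
        r = roi_fraction * ins.diameter / 2.0
        insert_masks.append(_disk_mask(X, Y, c, r))

    bg_radius = roi_fraction * max(i.diameter for i in spec.inserts) / 2.0
    if background_offsets is None:
        positions = _background_positions(spec, bg_radius, n_background)
    else:
        positions = [tuple(p) for p in background_offsets]
        for p in positions:
            if not spec.contains_disk(p, bg_radius):
                raise ConfigError(f"background ROI at {p} extends outside the body")
            for i, ins in enumerate(spec.inserts):
                d = math.hypot(p[0] - ins.center_xy[0], p[1] - ins.center_xy[1])
                if d < ins.diameter / 2.0 + bg_radius:
                    raise ConfigError(
                        f"background ROI at {p} overlaps insert {i} at {ins.center_xy}"
                    )
    background_masks = [_disk_mask(X, Y, p, bg_radius) for p in positions]
    return ROILayout(insert_masks, list(centers), background_masks)


def _select_slices(nz: int, slice_policy) -> np.ndarray:
    """Resolve a slice policy (central fraction or explicit indices)."""
    if np.isscalar(slice_policy):
        f = float(slice_policy)
        if not (0.0 < f <= 1.0):
            raise ConfigError(f"slice fraction must be in (0, 1], got {f}")
        k = max(1, int(round(nz * f)))
        start = (nz - k) // 2
        return np.arange(start, start + k)
    idx = np.asarray(list(slice_policy), dtype=int)
    if idx.size == 0:
        raise ConfigError("slice policy selects no slices")
    if np.any(idx < 0) or np.any(idx >= nz):
        raise ConfigError(f"slice indices {idx} out of range for {nz} slices")
    return idx


def roi_stats(image: ImageVolume, mask: np.ndarray, slice_policy=0.6, label: str = "") -> ROIStats:
    """Mean/SD over the masked voxels of the selected slices (pooled)."""
    idx = _select_slices(image.shape[0], slice_policy)
    if not mask.any():
        raise ConfigError("empty ROI mask")
    vox = image.voxels[idx][:, mask].ravel()
    sd = float(np.std(vox, ddof=1)) if vox.size > 1 else 0.0
    return ROIStats(float(np.mean(vox)), sd, int(vox.size), label)


def compute_cnr(insert: ROIStats, background: ROIStats, sd_override: float | None = None) -> float:
    """Signed contrast-to-noise ratio of an insert against the background.

    ``sd_override`` substitutes a nominal noise SD for the measured
    background SD (used for noise-free oracle checks).
    """
    sd = background.sd_hu if sd_override is None else float(sd_override)
    if sd <= 0:
        raise DegenerateInputError("background SD must be positive to compute CNR")
    return (insert.mean_hu - background.mean_hu) / sd


def measure_image(
    image: ImageVolume,
    spec: PhantomSpec,
    acq: AcquisitionSetting,
    roi_fraction: float = 0.7,
    slice_policy=0.6,
    mode: str = "geometry",
    layout: ROILayout | None = None,
    sd_override: float | None = None,
    enforce_min_voxels: bool = True,
) -> pd.DataFrame:
    """Measure CNR of every insert in one image; tidy one-row-per-insert table.

    A precomputed ``layout`` may be passed to amortise mask construction
    over replicate images of the same geometry.
    """
    if layout is None:
        layout = locate_rois(image, spec, roi_fraction=roi_fraction, mode=mode)
    bg = roi_stats(image, layout.background_mask, slice_policy, label="background")
    if enforce_min_voxels and bg.n_voxels < MIN_ROI_VOXELS:
        raise ConfigError(f"background ROI has only {bg.n_voxels} voxels (< {MIN_ROI_VOXELS})")
    rows = []
    for i, (ins, mask) in enumerate(zip(spec.inserts, layout.insert_masks)):
        st = roi_stats(image, mask, slice_policy, label=f"insert_{i}")
        if enforce_min_voxels and st.n_voxels < MIN_ROI_VOXELS:
            raise ConfigError(
                f"insert ROI {i} has only {st.n_voxels} voxels (< {MIN_ROI_VOXELS}); "
                "use a finer grid or larger roi_fraction"
            )
        cnr = compute_cnr(st, bg, sd_override=sd_override)
        rows.append(
            {
                "scanner_label": acq.scanner_label,
                "mode": acq.mode,
                "energy": acq.energy,
                "size_label": acq.size_label,
                "recon_label": acq.recon_label,
                "ctdi_vol": acq.ctdi_vol,
                "effective_diameter_cm": spec.effective_diameter_cm,
                "concentration_mg_ml": ins.concentration,
                "cnr": cnr,
                "insert_mean_hu": st.mean_hu,
                "insert_sd_hu": st.sd_hu,
                "insert_n_voxels": st.n_voxels,
                "background_mean_hu": bg.mean_hu,
                "background_sd_hu": bg.sd_hu,
                "background_n_voxels": bg.n_voxels,
            }
        )
    return pd.DataFrame(rows)


def spec_for_manifest_row(row) -> PhantomSpec:
    """Rebuild the phantom spec that produced a fixture-suite manifest row."""
    from .phantom import dect_phantom, sect_phantom
    from .simulate import SECT_STUDY

    if row["scanner_label"] in SECT_STUDY:
        spec = sect_phantom(row["size_label"], background_hu=float(row["background_hu"]))
    else:
        spec = dect_phantom(row["size_label"], background_hu=float(row["background_hu"]))
    conc = [float(c) for c in str(row["concentrations_mg_ml"]).split(";")]
    return spec.with_concentrations(conc)


def measure_suite(
    suite_dir,
    manifest: pd.DataFrame | None = None,
    roi_fraction: float = 0.7,
    slice_policy=0.6,
    mode: str = "geometry",
) -> pd.DataFrame:
    """Measure every volume of a generated fixture suite; tidy CNR table."""
    suite_dir = Path(suite_dir)
    if manifest is None:
        mpath = suite_dir / "manifest.csv"
        if not mpath.exists():
            raise ConfigError(f"no manifest.csv in {suite_dir}")
        manifest = pd.read_csv(mpath)
    frames = []
    for _, row in manifest.iterrows():
        path = suite_dir / str(row["file"])
        if path.suffix == ".npz":
            vol, _ = ImageVolume.load_npz(path)
        else:
            vol = ImageVolume.load_dicom_series(path)
        spec = spec_for_manifest_row(row)
        acq = AcquisitionSetting(
            row["mode"], float(row["energy"]), row["scanner_label"],
            row["recon_label"], float(row["ctdi_vol"]), row["size_label"],
        )
        frames.append(
            measure_image(vol, spec, acq, roi_fraction=roi_fraction,
                          slice_policy=slice_policy, mode=mode)
        )
    if not frames:
        raise ConfigError("manifest lists no volumes")
    return pd.concat(frames, ignore_index=True)
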