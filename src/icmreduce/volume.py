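"""HU image volumes and their on-disk containers.

Two containers are supported: a compressed numpy array with a JSON sidecar
(the default, round-trips HU exactly) and a minimal single-frame DICOM CT
series (int16 stored values with RescaleSlope/Intercept mapping to HU, for
interoperability with standard viewers).

Origin convention: the phantom centre sits at the image centre, and 0-based
indices address pixel centres, so pixel (i, j) of a (ny, nx) slice is at
physical x = (j - (nx-1)/2) * spacing, y = (i - (ny-1)/2) * spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError


@dataclass
class ImageVolume:
    """A 3-D HU voxel grid (slices x rows x cols) with physical spacing."""

    voxels: np.ndarray
    pixel_spacing: float  # mm, isotropic in-plane
    slice_thickness: float  # mm

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ConfigError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ConfigError("pixel spacing and slice thickness must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigError("voxels contain non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def xy_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (X, Y) coordinate grids (mm) of pixel centres for one slice."""
        nz, ny, nx = self.voxels.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_spacing
        return np.meshgrid(x, y)

    # ------------------------------------------------------------------ npz
    def save_npz(self, path, metadata: dict | None = None) -> None:
        """Write ``<path>.npz`` (compressed voxels) plus ``<path>.json`` sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), voxels=self.voxels)
        sidecar = {
            "pixel_spacing_mm": self.pixel_spacing,
            "slice_thickness_mm": self.slice_thickness,
            "shape": list(self.voxels.shape),
            "metadata": metadata or {},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def load_npz(cls, path) -> tuple["ImageVolume", dict]:
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            voxels = npz["voxels"]
        vol = cls(voxels, sidecar["pixel_spacing_mm"], sidecar["slice_thickness_mm"])
        return vol, sidecar.get("metadata", {})

    # ---------------------------------------------------------------- dicom
    def save_dicom_series(self, out_dir, series_description: str = "icmreduce", entropy: str = "0") -> list[Path]:
        """Write a minimal CT DICOM series, one int16 file per slice.

        Stored value = round(HU) with RescaleSlope 1 / RescaleIntercept 0,
        so HU round-trips to within 0.5.  UIDs are derived deterministically
        from ``entropy`` so identical runs produce identical series.
        """
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nz, ny, nx = self.voxels.shape
        study_uid = generate_uid(entropy_srcs=[entropy, "study"])
        series_uid = generate_uid(entropy_srcs=[entropy, "series"])
        frame_uid = generate_uid(entropy_srcs=[entropy, "frame"])
        paths = []
        for k in range(nz):
            sop_uid = generate_uid(entropy_srcs=[entropy, f"slice{k}"])
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = CTImageStorage
            meta.MediaStorageSOPInstanceUID = sop_uid
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = Dataset()
            ds.file_meta = meta
            ds.SOPClassUID = CTImageStorage
            ds.SOPInstanceUID = sop_uid
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.FrameOfReferenceUID = frame_uid
            ds.Modality = "CT"
            ds.SeriesDescription = series_description
            ds.PatientName = "PHANTOM"
            ds.PatientID = "PHANTOM"
            ds.InstanceNumber = k + 1
            ds.ImagePositionPatient = [
                -(nx - 1) / 2.0 * self.pixel_spacing,
                -(ny - 1) / 2.0 * self.pixel_spacing,
                k * self.slice_thickness,
            ]
            ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            ds.PixelSpacing = [self.pixel_spacing, self.pixel_spacing]
            ds.SliceThickness = self.slice_thickness
            ds.Rows, ds.Columns = ny, nx
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 1  # signed
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = 0.0
            ds.PixelData = np.round(self.voxels[k]).astype(np.int16).tobytes()
            p = out_dir / f"slice_{k:04d}.dcm"
            pydicom.dcmwrite(p, ds, enforce_file_format=True)
            paths.append(p)
        return paths

    @classmethod
    def load_dicom_series(cls, series_dir) -> "ImageVolume":
        """Read a single-frame CT series, applying RescaleSlope/Intercept."""
        import pydicom

        files = sorted(Path(series_dir).glob("*.dcm"))
        if not files:
            raise ConfigError(f"no .dcm files found in {series_dir}")
        datasets = [pydicom.dcmread(f) for f in files]
        datasets.sort(key=lambda d: (float(d.ImagePositionPatient[2]), int(d.InstanceNumber)))
        slices = []
        for ds in datasets:
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            slices.append(arr * slope + intercept)
        first = datasets[0]
        return cls(
            np.stack(slices),
            pixel_spacing=float(first.PixelSpacing[0]),
            slice_thickness=float(first.SliceThickness),
        )
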