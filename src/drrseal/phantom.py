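"""Synthetic CT phantom generation.

Writes deterministic single-frame DICOM series so the whole
seal-tamper-verify pipeline can run without any external data: ellipsoids
of distinct Hounsfield values on an air background (-1024 HU), optional
seeded Gaussian noise, configurable slice count/spacing, and optional
attribute defects (drop a tag, empty a value) for exercising validation.

Stored pixels are unsigned 16-bit with RescaleSlope 1 and RescaleIntercept
-1024 (stored = HU + 1024), a common CT encoding, so Hounsfield conversion
is exercised non-trivially.  The default geometry is 64x64 pixels by 40
slices with 0.5 mm pixels and 1.0 mm slice spacing, which makes the
isotropic z-resampling interpolate genuinely new planes while keeping a
full cycle down at desk scale (seconds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .dicom_io import HU_MAX, HU_MIN

logger = logging.getLogger(__name__)

_UID_ROOT = "1.2.826.0.1.3680043.10.1453"  # synthetic phantoms only


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates (z in slice-index units)."""

    center: tuple[float, float, float]  # (z, y, x)
    radii: tuple[float, float, float]  # (z, y, x)
    hu: int

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ValueError("ellipsoid radii must be positive")
        if not HU_MIN <= self.hu <= HU_MAX:
            raise ValueError(f"ellipsoid HU {self.hu} outside [{HU_MIN}, {HU_MAX}]")


@dataclass
class Defect:
    """An attribute defect injected into one slice for validation tests."""

    slice_index: int
    tag: str  # DICOM keyword, e.g. "PixelData"
    action: Literal["drop", "empty"] = "drop"


def default_shapes(n_slices: int, rows: int, cols: int) -> list[Ellipsoid]:
    """A body-like water ellipsoid plus soft-tissue and bone inclusions."""
    cz, cy, cx = n_slices / 2.0, rows / 2.0, cols / 2.0
    return [
        Ellipsoid((cz, cy, cx), (n_slices * 0.42, rows * 0.38, cols * 0.38), 0),
        Ellipsoid((cz, cy, cx - cols * 0.15), (n_slices * 0.2, rows * 0.16, cols * 0.14), 60),
        Ellipsoid((cz, cy, cx + cols * 0.18), (n_slices * 0.15, rows * 0.1, cols * 0.1), 700),
    ]


@dataclass
class PhantomSpec:
    """Full description of a synthetic series; same spec => same pixels."""

    rows: int = 64
    cols: int = 64
    n_slices: int = 40
    slice_spacing: float = 1.0  # mm
    pixel_spacing: float = 0.5  # mm
    background_hu: int = HU_MIN
    shapes: Optional[list[Ellipsoid]] = None
    noise_sigma: float = 5.0  # HU; typical quantum noise magnitude
    seed: int = 0
    defects: list[Defect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if self.slice_spacing <= 0 or self.pixel_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.shapes is None:
            self.shapes = default_shapes(self.n_slices, self.rows, self.cols)

    # -- JSON -----------------------------------------------------------

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        obj = json.loads(text)
        shapes = obj.pop("shapes", None)
        defects = obj.pop("defects", [])
        spec = cls(
            **obj,
            shapes=None
            if shapes is None
            else [
                Ellipsoid(tuple(s["center"]), tuple(s["radii"]), int(s["hu"]))
                for s in shapes
            ],
            defects=[
                Defect(int(d["slice_index"]), d["tag"], d.get("action", "drop"))
                for d in defects
            ],
        )
        return spec

    @classmethod
    def load(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def phantom_hu(spec: PhantomSpec) -> np.ndarray:
    """The analytic noise-free HU volume ``[z][y][x]`` the phantom encodes."""
    zz = np.arange(spec.n_slices, dtype=np.float64)[:, None, None]
    yy = np.arange(spec.rows, dtype=np.float64)[None, :, None]
    xx = np.arange(spec.cols, dtype=np.float64)[None, None, :]
    vol = np.full((spec.n_slices, spec.rows, spec.cols), float(spec.background_hu))
    for shape in spec.shapes or []:
        cz, cy, cx = shape.center
        rz, ry, rx = shape.radii
        mask = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        vol[mask] = float(shape.hu)
    return vol


def stored_pixel_volume(spec: PhantomSpec) -> np.ndarray:
    """Seeded stored-value (uint16) volume: HU + 1024, noise applied, clipped."""
    hu = phantom_hu(spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)
    stored = np.round(hu) + 1024.0
    return np.clip(stored, 0, HU_MAX + 1024).astype(np.uint16)


def _make_dataset(
    spec: PhantomSpec,
    index: int,
    pixels: np.ndarray,
    study_uid: str,
    series_uid: str,
) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = f"{_UID_ROOT}.{spec.seed}.3.{index + 1}"
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = f"SYN-{spec.seed:04d}"
    ds.InstanceNumber = index + 1
    ds.SliceLocation = format(index * spec.slice_spacing, ".6f")
    ds.ImagePositionPatient = ["0.0", "0.0", format(index * spec.slice_spacing, ".6f")]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.PixelSpacing = [format(spec.pixel_spacing, ".6f")] * 2
    ds.SliceThickness = format(spec.slice_spacing, ".6f")
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    ds.PixelData = np.ascontiguousarray(pixels).tobytes()
    return ds


def _apply_defect(ds: Dataset, defect: Defect) -> None:
    if defect.action == "drop":
        if defect.tag in ds:
            delattr(ds, defect.tag)
    elif defect.action == "empty":
        setattr(ds, defect.tag, None)
    else:
        raise ValueError(f"unknown defect action {defect.action!r}")


def generate_phantom(spec: PhantomSpec, out_dir: str | Path) -> list[Path]:
    """Write the phantom as one DICOM file per slice; returns the paths.

    Regeneration from the same spec is byte-identical in pixel content
    (UIDs are derived from the seed, so files repeat exactly too).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stored = stored_pixel_volume(spec)
    study_uid = f"{_UID_ROOT}.{spec.seed}.1"
    series_uid = f"{_UID_ROOT}.{spec.seed}.2"
    paths = []
    for i in range(spec.n_slices):
        ds = _make_dataset(spec, i, stored[i], study_uid, series_uid)
        for defect in spec.defects:
            if defect.slice_index == i:
                _apply_defect(ds, defect)
        path = out / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    logger.info("wrote %d phantom slices to %s", len(paths), out)
    return paths
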