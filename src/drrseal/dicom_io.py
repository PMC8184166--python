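"""DICOM series ingestion: reading, attribute validation, slice sorting,
Hounsfield conversion and isotropic volume reconstruction.

A CT series arrives as one single-frame DICOM file per axial slice.  Stored
pixel values relate to Hounsfield units (HU) through the affine rescale
``HU = stored * RescaleSlope + RescaleIntercept``; CT uses the nominal HU
range -1024 (air) to +3072.  Slices are ordered by Slice Location
(tag 0020,1041) and stacked into a 3D grid that is resampled along z so the
voxel edge equals the in-plane pixel spacing (isotropic voxels), using
linear interpolation between the two slices bracketing each output plane.

Array convention: volumes are indexed ``[z][y][x]`` with z the
superior-inferior stack axis, y the image row (anterior-posterior) and x
the image column (left-right).  Only z is ever resampled; in-plane data are
copied verbatim.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset
from pydicom.errors import InvalidDicomError

from .errors import (
    DegenerateSeriesError,
    EmptySeriesError,
    GeometryMismatchError,
    SeriesParseError,
    UnsortableSeriesError,
)

logger = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 3072

_SPACING_TOL = 1e-6


# --------------------------------------------------------------- containers

@dataclass
class SliceImage:
    """One validated 2D slice of a series.

    ``attributes`` keeps the full pydicom dataset so validation rules can
    inspect arbitrary tags and tampered slices can be re-serialized.
    ``stored_pixels`` is None when the file lacks Pixel Data (a defect that
    validation is expected to flag).
    """

    sop_instance_uid: str
    slice_location: Optional[float]
    instance_number: Optional[int]
    rows: int
    cols: int
    stored_pixels: Optional[np.ndarray]
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing: tuple[float, float]
    attributes: Dataset

    def __post_init__(self) -> None:
        if self.stored_pixels is not None:
            if self.stored_pixels.shape != (self.rows, self.cols):
                raise ValueError(
                    f"stored_pixels shape {self.stored_pixels.shape} does not "
                    f"match (rows, cols)=({self.rows}, {self.cols})"
                )
        if not math.isfinite(self.rescale_slope) or self.rescale_slope == 0:
            raise ValueError("rescale_slope must be finite and nonzero")
        if not math.isfinite(self.rescale_intercept):
            raise ValueError("rescale_intercept must be finite")


TypeClass = Literal["type1", "type2", "type1c"]
FailureKind = Literal["missing_tag", "empty_value", "condition_unmet"]


@dataclass(frozen=True)
class ValidationRule:
    """One DICOM attribute requirement.

    type1: tag and value mandatory; type2: tag mandatory, value optional;
    type1c: mandatory only when ``condition_tag`` is present with a value.
    Tags are DICOM keywords (e.g. ``"PixelData"``).
    """

    tag: str
    name: str
    type_class: TypeClass
    condition_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.type_class == "type1c") != (self.condition_tag is not None):
            raise ValueError("condition_tag is required iff type_class is type1c")


@dataclass(frozen=True)
class Finding:
    sop_instance_uid: str
    tag: str
    type_class: TypeClass
    failure_kind: FailureKind


@dataclass
class SeriesValidationReport:
    per_slice_findings: list[Finding] = field(default_factory=list)
    duplicate_uids: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.per_slice_findings and not self.duplicate_uids


@dataclass
class Volume:
    """Isotropic HU grid in ``[z][y][x]`` order."""

    hu: np.ndarray
    spacing: float
    n_slices_original: int
    provenance: list[str]

    def __post_init__(self) -> None:
        if self.hu.ndim != 3 or min(self.hu.shape) < 1:
            raise ValueError("volume must be a non-empty 3D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("volume HU values must be finite")


DEFAULT_RULES: tuple[ValidationRule, ...] = (
    ValidationRule("SOPClassUID", "SOP Class UID", "type1"),
    ValidationRule("SOPInstanceUID", "SOP Instance UID", "type1"),
    ValidationRule("Rows", "Rows", "type1"),
    ValidationRule("Columns", "Columns", "type1"),
    ValidationRule("BitsAllocated", "Bits Allocated", "type1"),
    ValidationRule("PixelData", "Pixel Data", "type1"),
    ValidationRule("PatientName", "Patient Name", "type2"),
    ValidationRule("PatientID", "Patient ID", "type2"),
    ValidationRule(
        "SliceLocation", "Slice Location", "type1c",
        condition_tag="ImagePositionPatient",
    ),
)


def load_rules(path: str | Path) -> list[ValidationRule]:
    """Load a validation rule set from a JSON config.

    Format: a list of objects ``{"tag", "name", "type_class", "condition_tag"}``
    with ``condition_tag`` present only for type1c rules.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        ValidationRule(
            tag=item["tag"],
            name=item.get("name", item["tag"]),
            type_class=item["type_class"],
            condition_tag=item.get("condition_tag"),
        )
        for item in raw
    ]


# ------------------------------------------------------------------ reading

def _float_or_none(ds: Dataset, kw: str) -> Optional[float]:
    v = getattr(ds, kw, None)
    if v in (None, ""):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def slice_from_dataset(ds: Dataset) -> SliceImage:
    """Build a SliceImage from a parsed pydicom dataset."""
    pixels = None
    rows = int(getattr(ds, "Rows", 0) or 0)
    cols = int(getattr(ds, "Columns", 0) or 0)
    if "PixelData" in ds and rows and cols:
        pixels = ds.pixel_array
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) == 2:
        px = (float(spacing[0]), float(spacing[1]))
    else:
        px = (1.0, 1.0)
    inst = getattr(ds, "InstanceNumber", None)
    return SliceImage(
        sop_instance_uid=str(getattr(ds, "SOPInstanceUID", "")),
        slice_location=_float_or_none(ds, "SliceLocation"),
        instance_number=int(inst) if inst not in (None, "") else None,
        rows=rows if pixels is None else pixels.shape[0],
        cols=cols if pixels is None else pixels.shape[1],
        stored_pixels=pixels,
        rescale_slope=_float_or_none(ds, "RescaleSlope") or 1.0,
        rescale_intercept=_float_or_none(ds, "RescaleIntercept") or 0.0,
        pixel_spacing=px,
        attributes=ds,
    )


def read_series(directory: str | Path) -> list[SliceImage]:
    """Read every parseable single-frame DICOM file in *directory*.

    Non-DICOM files are skipped with a logged warning; an unreadable DICOM
    file raises :class:`SeriesParseError` naming it; an empty directory (no
    DICOM at all) raises :class:`EmptySeriesError`.  Order is arbitrary
    (filename order here) — use :func:`sort_slices` before stacking.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise EmptySeriesError(f"{directory} is not a directory")
    slices: list[SliceImage] = []
    for path in sorted(p for p in directory.iterdir() if p.is_file()):
        try:
            ds = pydicom.dcmread(path)
        except InvalidDicomError:
            logger.warning("skipping non-DICOM file %s", path.name)
            continue
        except Exception as exc:  # broken DICOM
            raise SeriesParseError(f"cannot parse DICOM file {path.name}: {exc}") from exc
        try:
            slices.append(slice_from_dataset(ds))
        except Exception as exc:
            raise SeriesParseError(f"invalid slice in {path.name}: {exc}") from exc
    if not slices:
        raise EmptySeriesError(f"no DICOM files found in {directory}")
    logger.info("read %d slices from %s", len(slices), directory)
    return slices


def write_series(slices: Sequence[SliceImage], out_dir: str | Path) -> list[Path]:
    """Write slices back to single-frame DICOM files (one per slice).

    Pixel Data is refreshed from ``stored_pixels`` so tampered arrays are
    persisted.  Files are named by list position; SOP Instance UIDs may
    repeat (a duplicated IOD) without clobbering files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(slices):
        ds = s.attributes
        if s.stored_pixels is not None:
            ds.PixelData = np.ascontiguousarray(s.stored_pixels).tobytes()
            ds.Rows, ds.Columns = s.stored_pixels.shape
        path = out / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# --------------------------------------------------------------- validation

def _has_value(ds: Dataset, kw: str) -> bool:
    try:
        elem = ds[kw]
    except KeyError:
        return False
    return not elem.is_empty


def validate_series(
    slices: Sequence[SliceImage],
    rules: Iterable[ValidationRule] = DEFAULT_RULES,
) -> SeriesValidationReport:
    """Check DICOM attribute requirement classes over every slice.

    type1 rules flag a missing tag or an empty value; type2 only a missing
    tag; type1c flags the conditioned tag's absence only when the condition
    tag is present with a value.  SOP Instance UIDs occurring more than once
    are reported as duplicates (a finding, not an error, so adversarial
    duplicate-IOD series can still flow through the pipeline).
    """
    rules = list(rules)
    if not rules:
        raise ValueError("rules must be non-empty")
    findings: list[Finding] = []
    for s in slices:
        ds = s.attributes
        for rule in rules:
            present = rule.tag in ds
            if rule.type_class == "type1":
                if not present:
                    findings.append(Finding(s.sop_instance_uid, rule.tag, "type1", "missing_tag"))
                elif not _has_value(ds, rule.tag):
                    findings.append(Finding(s.sop_instance_uid, rule.tag, "type1", "empty_value"))
            elif rule.type_class == "type2":
                if not present:
                    findings.append(Finding(s.sop_instance_uid, rule.tag, "type2", "missing_tag"))
            else:  # type1c
                assert rule.condition_tag is not None
                if _has_value(ds, rule.condition_tag) and not present:
                    findings.append(
                        Finding(s.sop_instance_uid, rule.tag, "type1c", "condition_unmet")
                    )
    counts = Counter(s.sop_instance_uid for s in slices)
    dups = sorted(uid for uid, c in counts.items() if c > 1)
    report = SeriesValidationReport(per_slice_findings=findings, duplicate_uids=dups)
    if not report.is_valid:
        logger.warning(
            "series validation failed: %d findings, %d duplicate UIDs",
            len(findings), len(dups),
        )
    return report


# ------------------------------------------------------------------ sorting

def sort_slices(slices: Sequence[SliceImage]) -> list[SliceImage]:
    """Order slices along the stack axis.

    Primary key is Slice Location ascending, ties broken by Instance Number
    then SOP Instance UID.  When no slice carries a location but all carry
    an instance number, instance-number order is used instead.
    """
    if not slices:
        return []
    if all(s.slice_location is not None for s in slices):
        return sorted(
            slices,
            key=lambda s: (
                s.slice_location,
                s.instance_number is None,
                s.instance_number if s.instance_number is not None else 0,
                s.sop_instance_uid,
            ),
        )
    if all(s.instance_number is not None for s in slices):
        return sorted(slices, key=lambda s: (s.instance_number, s.sop_instance_uid))
    raise UnsortableSeriesError(
        "series cannot be sorted: slice_location is not present on every "
        "slice and instance_number is not present on every slice"
    )


# ------------------------------------------------------- HU and the volume

def to_hu(slc: SliceImage) -> np.ndarray:
    """Convert stored pixel values to Hounsfield units (no clamping)."""
    if slc.stored_pixels is None:
        raise ValueError("slice has no pixel data")
    return slc.stored_pixels.astype(np.float64) * slc.rescale_slope + slc.rescale_intercept


def _stack_positions(sorted_slices: Sequence[SliceImage], spacing: float) -> np.ndarray:
    locs = [s.slice_location for s in sorted_slices]
    if all(l is not None for l in locs):
        return np.asarray(locs, dtype=np.float64)
    # No uniform Slice Location: stack by index at the in-plane spacing so
    # the result is an identity (non-resampled) stack.
    logger.warning("no uniform SliceLocation; stacking by index without resampling")
    return np.arange(len(sorted_slices), dtype=np.float64) * spacing


def build_volume(sorted_slices: Sequence[SliceImage]) -> Volume:
    """Stack sorted slices into an isotropic HU volume.

    The target voxel edge is the in-plane pixel spacing.  Output planes are
    placed from the first to the last slice location at that step; each is
    linearly interpolated between the two bracketing acquired slices by
    location distance, or copied exactly when it coincides with one.
    Non-uniform acquisition spacing is supported.
    """
    if len(sorted_slices) < 2:
        raise DegenerateSeriesError("at least 2 slices are required to build a volume")
    first = sorted_slices[0]
    for s in sorted_slices:
        if s.stored_pixels is None:
            raise GeometryMismatchError(
                f"slice {s.sop_instance_uid or '<no uid>'} has no pixel data"
            )
        if (s.rows, s.cols) != (first.rows, first.cols):
            raise GeometryMismatchError(
                f"slice {s.sop_instance_uid}: rows/cols {(s.rows, s.cols)} "
                f"differ from {(first.rows, first.cols)}"
            )
        if (abs(s.pixel_spacing[0] - first.pixel_spacing[0]) > _SPACING_TOL
                or abs(s.pixel_spacing[1] - first.pixel_spacing[1]) > _SPACING_TOL):
            raise GeometryMismatchError(
                f"slice {s.sop_instance_uid}: pixel spacing {s.pixel_spacing} "
                f"differs from {first.pixel_spacing}"
            )
    if abs(first.pixel_spacing[0] - first.pixel_spacing[1]) > _SPACING_TOL:
        raise GeometryMismatchError(
            f"in-plane spacing must be square, got {first.pixel_spacing}"
        )
    spacing = float(first.pixel_spacing[0])
    locs = _stack_positions(sorted_slices, spacing)
    if np.any(np.diff(locs) < 0):
        raise ValueError("slices must be sorted by location before build_volume")
    z0, z_last = float(locs[0]), float(locs[-1])
    if z_last == z0:
        raise DegenerateSeriesError("all slice locations are equal; no z extent")

    hu_in = np.stack([to_hu(s) for s in sorted_slices])
    n_out = int(math.floor((z_last - z0) / spacing + 1e-9)) + 1
    planes = np.empty((n_out, first.rows, first.cols), dtype=np.float64)
    rel_tol = _SPACING_TOL * max(1.0, abs(z0), abs(z_last))
    for k in range(n_out):
        z = z0 + k * spacing
        j = int(np.searchsorted(locs, z, side="right")) - 1
        j = min(max(j, 0), len(locs) - 2)
        if abs(locs[j] - z) <= rel_tol:
            planes[k] = hu_in[j]
        elif abs(locs[j + 1] - z) <= rel_tol:
            planes[k] = hu_in[j + 1]
        else:
            dz = locs[j + 1] - locs[j]
            w = (z - locs[j]) / dz
            planes[k] = (1.0 - w) * hu_in[j] + w * hu_in[j + 1]
    return Volume(
        hu=planes,
        spacing=spacing,
        n_slices_original=len(sorted_slices),
        provenance=[s.sop_instance_uid for s in sorted_slices],
    )
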