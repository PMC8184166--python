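"""Digitally reconstructed radiograph (DRR) computation.

The DRR used for sealing is an orthographic *mean* projection of the HU
volume along one patient axis: every output pixel is the average of the HU
values on the ray passing through it.  Three principal directions are
supported:

* ``coronal``  — average over y (anterior-posterior), image is (z, x)
* ``sagittal`` — average over x (left-right), image is (z, y)
* ``axial``    — average over z (superior-inferior), image is (y, x)

Pixels stay at full float64 precision: a +-10 HU change in one of N slices
moves a projected pixel by only 10/N, which integer quantization could
erase.  Quantization (round half away from zero, clamp to the HU range) is
applied only when histograms are built.  Summation runs in ascending index
order with numpy's deterministic pairwise accumulation, so identical input
volumes produce bit-identical DRRs — the property the verification stage
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from .dicom_io import HU_MAX, HU_MIN, Volume

Direction = Literal["axial", "coronal", "sagittal"]

DIRECTIONS: tuple[Direction, ...] = ("axial", "coronal", "sagittal")

#: volume axis averaged out for each projection direction ([z][y][x] order)
_PROJECTION_AXIS: dict[str, int] = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass
class DRRImage:
    """A 2D mean-projection image tagged with its direction.

    ``source_extents`` records the (nz, ny, nx) of the projected volume so a
    receiver can cross-check geometry.
    """

    pixels: np.ndarray
    direction: Direction
    source_extents: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("DRR pixels must be 2D")
        if self.direction not in _PROJECTION_AXIS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def compute_drr(volume: Volume, direction: Direction) -> DRRImage:
    """Mean-project *volume* along the axis of *direction*.

    coronal: pixels[z][x] = mean over y; sagittal: pixels[z][y] = mean over
    x; axial: pixels[y][x] = mean over z.
    """
    axis = _PROJECTION_AXIS.get(direction)
    if axis is None:
        raise ValueError(f"unknown direction {direction!r}")
    hu = volume.hu
    n = hu.shape[axis]
    pixels = np.add.reduce(hu, axis=axis, dtype=np.float64) / n
    return DRRImage(
        pixels=pixels,
        direction=direction,
        source_extents=(hu.shape[0], hu.shape[1], hu.shape[2]),
    )


def quantize_pixels(
    pixels: np.ndarray, lo: int = HU_MIN, hi: int = HU_MAX
) -> np.ndarray:
    """Round half away from zero to integers, then clamp to [lo, hi]."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    arr = np.asarray(pixels, dtype=np.float64)
    rounded = np.floor(np.abs(arr) + 0.5) * np.sign(arr)
    return np.clip(rounded, lo, hi).astype(np.int64)


def quantize_drr(drr: Union[DRRImage, np.ndarray], lo: int = HU_MIN, hi: int = HU_MAX) -> np.ndarray:
    """Integer-quantized copy of a DRR (or raw 2D array) for histogramming."""
    pixels = drr.pixels if isinstance(drr, DRRImage) else drr
    return quantize_pixels(pixels, lo, hi)


def export_png(
    drr: DRRImage,
    path: str,
    window_center: float = -200.0,
    window_width: float = 1500.0,
) -> None:
    """Write a window/levelled 8-bit PNG of the DRR for visual inspection.

    Display-only: the greyscale mapping (DICOM window center/width) is never
    used by sealing or verification.
    """
    from PIL import Image

    lo = window_center - window_width / 2.0
    grey = np.clip((drr.pixels - lo) / window_width, 0.0, 1.0)
    Image.fromarray((grey * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)
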