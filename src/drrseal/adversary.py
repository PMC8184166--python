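"""Simulated adversarial edits on a DICOM series.

Models the three canonical image-injection attacks against an in-transit
series: inserting an image (a foreign slice or a duplicated IOD from the
same series), deleting an image, and modifying pixel intensities by a small
HU amount (default magnitude 10, signs random per pixel).  All operations
are pure — the input list is untouched — and deterministic given the seed,
so detection experiments are repeatable.

``tamper_series`` applies an operation file-to-file so the attack can be
exercised on disk exactly as it would occur on the wire.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np

from .dicom_io import SliceImage, read_series, sort_slices, write_series

logger = logging.getLogger(__name__)

TamperKind = Literal["insert", "delete", "modify"]
SignMode = Literal["random", "positive"]


@dataclass
class TamperOp:
    """One adversarial edit.

    ``target_index`` addresses the sorted series.  For ``insert``,
    ``source`` is either the string ``"duplicate"`` (re-insert the slice at
    target_index, keeping its SOP Instance UID) or a foreign
    :class:`SliceImage`.  For ``modify``, ``amplitude`` is the signed HU
    shift magnitude applied to ``n_pixels`` randomly chosen pixels
    (``"all"`` for every pixel), with the sign drawn per pixel unless
    ``signs="positive"``.
    """

    kind: TamperKind
    target_index: int = 0
    source: Union[str, SliceImage] = "duplicate"
    amplitude: int = 10
    n_pixels: Union[int, str] = "all"
    seed: int = 0
    signs: SignMode = "random"


def _copy_slice(s: SliceImage) -> SliceImage:
    return copy.deepcopy(s)


def insert_image(series: Sequence[SliceImage], op: TamperOp) -> list[SliceImage]:
    """Insert a duplicated or foreign slice at ``target_index``.

    A duplicated slice keeps its SOP Instance UID, creating the
    duplicate-UID condition that series validation reports.
    """
    if op.kind != "insert":
        raise ValueError("op.kind must be 'insert'")
    out = list(series)
    if isinstance(op.source, SliceImage):
        inserted = _copy_slice(op.source)
    elif op.source == "duplicate":
        if not 0 <= op.target_index < len(series):
            raise IndexError(f"target_index {op.target_index} out of bounds")
        inserted = _copy_slice(series[op.target_index])
    else:
        raise ValueError(f"unknown insert source {op.source!r}")
    out.insert(min(max(op.target_index, 0), len(out)), inserted)
    logger.info("inserted slice at index %d (now %d slices)", op.target_index, len(out))
    return out


def delete_image(series: Sequence[SliceImage], op: TamperOp) -> list[SliceImage]:
    """Remove the slice at ``target_index``; the series must keep >= 2 slices."""
    if op.kind != "delete":
        raise ValueError("op.kind must be 'delete'")
    if len(series) < 3:
        raise ValueError("series must have at least 3 slices to delete one")
    if not 0 <= op.target_index < len(series):
        raise IndexError(f"target_index {op.target_index} out of bounds")
    out = list(series)
    del out[op.target_index]
    logger.info("deleted slice %d (now %d slices)", op.target_index, len(out))
    return out


def modify_pixels(series: Sequence[SliceImage], op: TamperOp) -> list[SliceImage]:
    """Shift randomly chosen pixels of one slice by exactly +-amplitude HU.

    Stored values move by ``amplitude / rescale_slope`` so the HU shift is
    exact; the shift must therefore be an integer in stored units.  Values
    are clipped to the stored dtype's range (air pixels cannot go below
    stored 0), which only matters for negative signs.
    """
    if op.kind != "modify":
        raise ValueError("op.kind must be 'modify'")
    if op.amplitude == 0:
        raise ValueError("amplitude must be nonzero for modify")
    if not 0 <= op.target_index < len(series):
        raise IndexError(f"target_index {op.target_index} out of bounds")
    target = _copy_slice(series[op.target_index])
    if target.stored_pixels is None:
        raise ValueError("target slice has no pixel data")
    stored_shift = op.amplitude / target.rescale_slope
    if abs(stored_shift - round(stored_shift)) > 1e-9:
        raise ValueError(
            f"amplitude {op.amplitude} HU is not an integer number of stored "
            f"units at slope {target.rescale_slope}"
        )
    stored_shift = int(round(stored_shift))

    rng = np.random.default_rng(op.seed)
    flat = target.stored_pixels.astype(np.int64).ravel()
    if op.n_pixels == "all":
        idx = np.arange(flat.size)
    else:
        n = int(op.n_pixels)
        if n < 1:
            raise ValueError("n_pixels must be positive or 'all'")
        idx = rng.choice(flat.size, size=min(n, flat.size), replace=False)
    if op.signs == "positive":
        sign = np.ones(idx.size, dtype=np.int64)
    else:
        sign = rng.choice(np.array([-1, 1], dtype=np.int64), size=idx.size)
    flat[idx] += sign * stored_shift

    dtype = target.stored_pixels.dtype
    info = np.iinfo(dtype) if np.issubdtype(dtype, np.integer) else None
    if info is not None:
        clipped = np.clip(flat, info.min, info.max)
        if not np.array_equal(clipped, flat):
            logger.warning("modify_pixels clipped values at the stored dtype range")
        flat = clipped
    target.stored_pixels = flat.reshape(target.stored_pixels.shape).astype(dtype)

    out = list(series)
    out[op.target_index] = target
    logger.info(
        "modified %d pixels of slice %d by %+d HU (%s signs)",
        idx.size, op.target_index, op.amplitude, op.signs,
    )
    return out


_DISPATCH = {"insert": insert_image, "delete": delete_image, "modify": modify_pixels}


def apply_tamper(series: Sequence[SliceImage], op: TamperOp) -> list[SliceImage]:
    """Dispatch on ``op.kind``."""
    return _DISPATCH[op.kind](series, op)


def tamper_series(
    in_dir: str | Path,
    out_dir: str | Path,
    op: TamperOp,
) -> list[Path]:
    """Read a series, apply one tamper op in sorted order, write it back."""
    slices = sort_slices(read_series(in_dir))
    return write_series(apply_tamper(slices, op), out_dir)
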