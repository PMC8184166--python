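"""Sealing: zig-zag block partition, AES encryption and the sidecar manifest.

The sender splits the DRR into an equal grid (4x4 by default, 8x8
supported), walks the blocks in JPEG-style zig-zag order so they are not
transmitted sequentially, serializes each block deterministically and
encrypts it independently with AES-256-CBC under a key derived from a user
passphrase (salted PBKDF2).  The resulting ciphertexts travel next to the
DICOM dataset in a JSON sidecar — the *sealed manifest* — which also pins
every parameter the receiver needs to rebuild the comparison bit-for-bit:
grid, traversal version, serialization dialect, KDF parameters, padding and
the projection direction.

No MAC is attached: integrity is established by regenerating the DRR at the
receiver and comparing content, not by authenticating ciphertext.
"""

from __future__ import annotations

import base64
import json
import logging
import os
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import _aes
from .drr import Direction, DRRImage
from .errors import BlockGridError, MalformedManifestError, SerializationError, WrongKeyError

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"
ZIGZAG_ID = "jpeg-zigzag-v1"
SERIALIZATION_ID = "f64le-rowmajor-v1"
DEFAULT_GRID = (4, 4)
DEFAULT_KDF_ITERATIONS = 200_000
DEFAULT_PAD_VALUE = -1024.0  # air


# ------------------------------------------------------------------ zig-zag

def zigzag_order(g_rows: int, g_cols: int) -> list[int]:
    """1-based row-major block labels in JPEG zig-zag traversal order.

    Starts at the top-left block, first step to the right, then alternates
    direction along successive anti-diagonals.  For a 4x4 grid the third
    block visited is label 5 (row 2, column 1).
    """
    if g_rows < 1 or g_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    order: list[int] = []
    for s in range(g_rows + g_cols - 1):
        r_lo = max(0, s - g_cols + 1)
        r_hi = min(s, g_rows - 1)
        rows = range(r_hi, r_lo - 1, -1) if s % 2 == 0 else range(r_lo, r_hi + 1)
        for r in rows:
            c = s - r
            order.append(r * g_cols + c + 1)
    return order


# ---------------------------------------------------------------- blocking

@dataclass
class BlockSet:
    """Equal-size DRR blocks in zig-zag traversal order.

    ``labels[i]`` is the 1-based row-major position of ``blocks[i]`` in the
    original image; reassembling by label reconstructs the DRR exactly.
    """

    blocks: list[np.ndarray]
    grid: tuple[int, int]
    labels: list[int]
    block_shape: tuple[int, int]

    def __post_init__(self) -> None:
        n = self.grid[0] * self.grid[1]
        if sorted(self.labels) != list(range(1, n + 1)):
            raise ValueError("labels must be a permutation of 1..g_rows*g_cols")
        if len(self.blocks) != n:
            raise ValueError("block count must equal g_rows*g_cols")


def pad_to_grid(
    pixels: np.ndarray,
    grid: tuple[int, int],
    pad_value: float = DEFAULT_PAD_VALUE,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad bottom/right edges with *pad_value* until divisible by *grid*."""
    g_rows, g_cols = grid
    pad_r = (-pixels.shape[0]) % g_rows
    pad_c = (-pixels.shape[1]) % g_cols
    if pad_r == 0 and pad_c == 0:
        return pixels, (0, 0)
    padded = np.pad(pixels, ((0, pad_r), (0, pad_c)), constant_values=pad_value)
    return padded, (pad_r, pad_c)


def partition_blocks(
    drr: DRRImage | np.ndarray,
    grid: tuple[int, int] = DEFAULT_GRID,
    pad: bool = False,
    pad_value: float = DEFAULT_PAD_VALUE,
) -> BlockSet:
    """Split a DRR into an equal grid and reorder blocks in zig-zag order.

    By default the image dimensions must divide evenly; with ``pad=True``
    the bottom/right edges are padded with air first (the same padding must
    then be applied by the receiver — the manifest records it).
    """
    pixels = drr.pixels if isinstance(drr, DRRImage) else np.asarray(drr)
    g_rows, g_cols = grid
    if g_rows < 1 or g_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if pad:
        pixels, _ = pad_to_grid(pixels, grid, pad_value)
    if pixels.shape[0] % g_rows:
        raise BlockGridError(
            f"DRR row count {pixels.shape[0]} not divisible by grid rows {g_rows}"
        )
    if pixels.shape[1] % g_cols:
        raise BlockGridError(
            f"DRR column count {pixels.shape[1]} not divisible by grid cols {g_cols}"
        )
    br, bc = pixels.shape[0] // g_rows, pixels.shape[1] // g_cols
    labels = zigzag_order(g_rows, g_cols)
    blocks = []
    for label in labels:
        r, c = divmod(label - 1, g_cols)
        blocks.append(np.ascontiguousarray(pixels[r * br : (r + 1) * br, c * bc : (c + 1) * bc]))
    return BlockSet(blocks=blocks, grid=grid, labels=labels, block_shape=(br, bc))


def reassemble_blocks(blockset: BlockSet) -> np.ndarray:
    """Inverse of :func:`partition_blocks` (returns the padded image)."""
    g_rows, g_cols = blockset.grid
    br, bc = blockset.block_shape
    out = np.empty((g_rows * br, g_cols * bc), dtype=np.float64)
    for label, block in zip(blockset.labels, blockset.blocks):
        r, c = divmod(label - 1, g_cols)
        out[r * br : (r + 1) * br, c * bc : (c + 1) * bc] = block
    return out


# ------------------------------------------------------------ serialization

def serialize_block(block: np.ndarray) -> bytes:
    """Deterministic byte form: <rows><cols> as uint32 LE, then float64 LE
    elements row-major."""
    arr = np.ascontiguousarray(block, dtype=np.float64)
    if arr.ndim != 2:
        raise SerializationError("block must be 2D")
    if not np.all(np.isfinite(arr)):
        raise SerializationError("block values must be finite")
    header = struct.pack("<II", arr.shape[0], arr.shape[1])
    return header + arr.astype("<f8").tobytes(order="C")


def deserialize_block(data: bytes) -> np.ndarray:
    if len(data) < 8:
        raise SerializationError("block byte stream shorter than its header")
    rows, cols = struct.unpack("<II", data[:8])
    expected = 8 + rows * cols * 8
    if rows == 0 or cols == 0 or len(data) != expected:
        raise SerializationError(
            f"block byte stream length {len(data)} inconsistent with "
            f"declared shape ({rows}, {cols})"
        )
    return np.frombuffer(data[8:], dtype="<f8").reshape(rows, cols).copy()


# ----------------------------------------------------------------- manifest

@dataclass
class SealedEntry:
    label: int
    iv: bytes
    ciphertext: bytes


@dataclass
class SealedManifest:
    """Sidecar carrying the encrypted DRR blocks and comparison parameters."""

    direction: Direction
    drr_shape: tuple[int, int]  # sealed (post-padding) shape
    grid: tuple[int, int]
    kdf_salt: bytes
    kdf_iterations: int
    entries: list[SealedEntry]
    source_image_count: Optional[int] = None
    padding: tuple[int, int] = (0, 0)
    pad_value: float = DEFAULT_PAD_VALUE
    format_version: str = FORMAT_VERSION
    zigzag_id: str = ZIGZAG_ID
    serialization: str = SERIALIZATION_ID

    def validate(self) -> None:
        g_rows, g_cols = self.grid
        expected = zigzag_order(g_rows, g_cols)
        if [e.label for e in self.entries] != expected:
            raise MalformedManifestError(
                f"manifest entries do not form the {g_rows}x{g_cols} zig-zag "
                f"permutation (got {len(self.entries)} entries)"
            )
        ivs = [e.iv for e in self.entries]
        if len(set(ivs)) != len(ivs):
            raise MalformedManifestError("IVs are not unique within the manifest")
        if self.drr_shape[0] % g_rows or self.drr_shape[1] % g_cols:
            raise MalformedManifestError("drr_shape is not divisible by the grid")
        if self.kdf_iterations < 1:
            raise MalformedManifestError("KDF iteration count must be positive")

    # -- JSON (binary fields base64) ------------------------------------

    def to_json(self) -> str:
        obj = {
            "format_version": self.format_version,
            "direction": self.direction,
            "drr_shape": list(self.drr_shape),
            "grid": list(self.grid),
            "zigzag_id": self.zigzag_id,
            "serialization": self.serialization,
            "kdf": {
                "salt": base64.b64encode(self.kdf_salt).decode("ascii"),
                "iterations": self.kdf_iterations,
            },
            "padding": list(self.padding),
            "pad_value": self.pad_value,
            "source_image_count": self.source_image_count,
            "entries": [
                {
                    "label": e.label,
                    "iv": base64.b64encode(e.iv).decode("ascii"),
                    "ciphertext": base64.b64encode(e.ciphertext).decode("ascii"),
                }
                for e in self.entries
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SealedManifest":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise MalformedManifestError(f"manifest is not valid JSON: {exc}") from exc
        try:
            if obj["format_version"] != FORMAT_VERSION:
                raise MalformedManifestError(
                    f"unsupported manifest format_version {obj['format_version']!r}"
                )
            manifest = cls(
                direction=obj["direction"],
                drr_shape=tuple(obj["drr_shape"]),
                grid=tuple(obj["grid"]),
                kdf_salt=base64.b64decode(obj["kdf"]["salt"]),
                kdf_iterations=int(obj["kdf"]["iterations"]),
                entries=[
                    SealedEntry(
                        label=int(e["label"]),
                        iv=base64.b64decode(e["iv"]),
                        ciphertext=base64.b64decode(e["ciphertext"]),
                    )
                    for e in obj["entries"]
                ],
                source_image_count=obj.get("source_image_count"),
                padding=tuple(obj.get("padding", (0, 0))),
                pad_value=float(obj.get("pad_value", DEFAULT_PAD_VALUE)),
                zigzag_id=obj.get("zigzag_id", ZIGZAG_ID),
                serialization=obj.get("serialization", SERIALIZATION_ID),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise MalformedManifestError(f"manifest structure invalid: {exc}") from exc
        if manifest.zigzag_id != ZIGZAG_ID or manifest.serialization != SERIALIZATION_ID:
            raise MalformedManifestError("unsupported traversal or serialization dialect")
        manifest.validate()
        return manifest

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SealedManifest":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


# ------------------------------------------------------------- seal/unseal

def seal(
    drr: DRRImage,
    passphrase: str,
    grid: tuple[int, int] = DEFAULT_GRID,
    direction: Optional[Direction] = None,
    *,
    pad: bool = False,
    pad_value: float = DEFAULT_PAD_VALUE,
    source_image_count: Optional[int] = None,
    kdf_iterations: int = DEFAULT_KDF_ITERATIONS,
    salt: Optional[bytes] = None,
) -> SealedManifest:
    """Encrypt the zig-zag blocks of *drr* under *passphrase*.

    A 256-bit key is derived with salted PBKDF2; each serialized block is
    encrypted independently with AES-CBC/PKCS#7 under a fresh random IV.
    ``source_image_count`` should be the number of DICOM files sealed, so
    the receiver can detect insertions/deletions that the location-resampled
    volume would absorb.
    """
    if not passphrase:
        raise ValueError("passphrase must be non-empty")
    direction = direction or drr.direction
    pixels = drr.pixels
    if pad:
        pixels, pad_rc = pad_to_grid(pixels, grid, pad_value)
    else:
        pad_rc = (0, 0)
    blockset = partition_blocks(pixels, grid)
    if salt is None:
        salt = os.urandom(16)
    key = _aes.derive_key(passphrase, salt, kdf_iterations)
    entries = []
    seen_ivs: set[bytes] = set()
    for label, block in zip(blockset.labels, blockset.blocks):
        iv = os.urandom(16)
        while iv in seen_ivs:  # pragma: no cover - astronomically unlikely
            iv = os.urandom(16)
        seen_ivs.add(iv)
        entries.append(
            SealedEntry(label=label, iv=iv, ciphertext=_aes.cbc_encrypt(key, iv, serialize_block(block)))
        )
    manifest = SealedManifest(
        direction=direction,
        drr_shape=(pixels.shape[0], pixels.shape[1]),
        grid=grid,
        kdf_salt=salt,
        kdf_iterations=kdf_iterations,
        entries=entries,
        source_image_count=source_image_count,
        padding=pad_rc,
        pad_value=pad_value,
    )
    manifest.validate()
    logger.info(
        "sealed %s DRR %sx%s into %d blocks (%s grid)",
        direction, pixels.shape[0], pixels.shape[1], len(entries), grid,
    )
    return manifest


def unseal(manifest: SealedManifest, passphrase: str) -> BlockSet:
    """Decrypt the manifest's blocks; inverse of :func:`seal`.

    A PKCS#7 padding failure or a garbage block header is reported as
    :class:`WrongKeyError` — with a wrong passphrase AES-CBC usually (but
    not always) fails padding, so callers must still compare content.
    """
    manifest.validate()
    g_rows, g_cols = manifest.grid
    br = manifest.drr_shape[0] // g_rows
    bc = manifest.drr_shape[1] // g_cols
    key = _aes.derive_key(passphrase, manifest.kdf_salt, manifest.kdf_iterations)
    blocks = []
    for entry in manifest.entries:
        try:
            plain = _aes.cbc_decrypt(key, entry.iv, entry.ciphertext)
            block = deserialize_block(plain)
        except (_aes.PaddingError, SerializationError) as exc:
            raise WrongKeyError(
                f"block {entry.label}: wrong passphrase or corrupted ciphertext ({exc})"
            ) from exc
        if block.shape != (br, bc):
            raise WrongKeyError(
                f"block {entry.label}: decrypted shape {block.shape} does not "
                f"match manifest geometry ({br}, {bc})"
            )
        blocks.append(block)
    return BlockSet(
        blocks=blocks,
        grid=manifest.grid,
        labels=[e.label for e in manifest.entries],
        block_shape=(br, bc),
    )
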