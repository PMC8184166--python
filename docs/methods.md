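# Methods

## Problem and model

A volumetric radiology series is a set of single-frame DICOM files, one per
axial slice. The integrity target is the *dataset*, not any single file:
the attacks of interest are inserting an image (foreign or a duplicated
IOD), deleting an image, and modifying pixel intensities by a small amount
(±10 HU is the canonical magnitude for a visually imperceptible edit).

The scheme derives a single fingerprint image — a digitally reconstructed
radiograph (DRR) — from the whole volume, seals it with a symmetric cipher,
and has the receiver regenerate and compare. Because every DRR pixel is a
mean over an entire projection ray, any slice-level change moves some DRR
pixels, and because sender and receiver run the *same deterministic
pipeline*, "unchanged" is exactly zero rather than "small".

## Pipeline details and numerical choices

**Validation.** Attribute requirements follow the DICOM type classes:
type 1 (tag and value mandatory), type 2 (tag mandatory, value optional),
type 1c (conditionally mandatory). The default rule set covers SOP Class/
Instance UID, Rows, Columns, Bits Allocated, Pixel Data (type 1), Patient
Name/ID (type 2) and one type-1c placeholder (Slice Location conditional on
Image Position (Patient)); rule sets are loadable from JSON because the
type classes, not a specific tag list, are the contract. Duplicate SOP
Instance UIDs are a *finding*, not a hard error, so adversarial series
still flow through the pipeline and are judged at verification.

**Geometry.** Arrays are `[z][y][x]`, z the stack axis sorted by Slice
Location ascending (ties: Instance Number, then UID). Hounsfield conversion
is the affine rescale with no clamping. The volume is resampled *only
along z*: output planes run from the first to the last slice location at a
step equal to the in-plane pixel spacing (isotropic voxels), each plane
linearly interpolated between its two bracketing acquired slices by
location distance, or copied bit-exactly when it coincides with one
(tolerance 1e-6 mm, relative). Non-uniform acquisition spacing is
supported. When no slice carries a location but all carry instance
numbers, slices are stacked by index without resampling — a pragmatic
fallback for location-less modalities.

**Projection.** The DRR is the mean of HU along one principal axis
(coronal = over y, sagittal = over x, axial = over z). Pixels are kept in
float64: a ±10 HU edit in one slice of N shifts a ray mean by 10/N
(~0.13 HU at N=79), which integer DRR pixels would often round away.
Summation uses numpy's deterministic ascending pairwise reduction, so
identical volumes give bit-identical DRRs — the foundation of the
exact-zero PASS criterion.

**Quantization.** Histograms need integer support, so block pixels are
rounded half away from zero and clamped to the HU range [−1024, +3072]
(configurable; the CT convention is the default, and no claim is made that
this range is meaningful for MRI intensities).

**Blocking.** Default grid 4×4 (16 blocks; 128×128 blocks for a 512×512
image, 64×64 for 256×256), 8×8 supported for finer localisation. Blocks
are transmitted in JPEG-style zig-zag order (anti-diagonals, first step
right) so an adversary cannot trivially reassemble the fingerprint from
transmission order; block-level comparison also defeats an image-level
histogram forgery, since matching sixteen local histograms simultaneously
is much harder than matching one global one. Non-divisible DRR shapes are
a hard error at the library level; callers may opt into bottom/right air
padding (−1024), which the manifest records so the receiver pads
identically. The bench/CLI workflows enable padding because arbitrary
slice counts rarely divide the grid.

**Sealing.** Serialization is fixed little-endian: two uint32 dimensions
then row-major float64 — the manifest pins this dialect plus the traversal
version, so both ends agree byte-for-byte. Keys are 256-bit, derived by
PBKDF2-HMAC-SHA256 with a random 16-byte salt and 200 000 iterations
(interactive-use cost; configurable). Each block is encrypted
independently with AES-CBC and PKCS#7 under a fresh random IV; per-block
independence means a single corrupted ciphertext still localises to one
block. No MAC is attached deliberately: integrity is established by
comparing decrypted content against the regenerated DRR, not by
authenticating bytes. AES itself is implemented in-package (the S-box
generated from its GF(2⁸) definition) and pinned to the FIPS-197 and NIST
SP 800-38A known-answer vectors in the test suite.

**Verdict.** PASS requires *all* of: no structural findings (validation
findings, duplicate UIDs, a file count differing from the manifest's
`source_image_count`, decryption failure, shape/padding mismatch), every
per-block histogram L1 difference equal to 0, and RMSE exactly 0.0.
Using the conjunction of both metrics is the conservative reading of
"histogram difference or RMSE"; they are cheap and catch different
failure surfaces (quantized distribution vs. sub-quantum float shifts).
Verification never raises for data-dependent problems — every failure is a
FAIL report with reasons, because a verifier that crashes on adversarial
input is itself a vulnerability.

## Synthetic phantoms: what they emulate and what they don't

`PhantomSpec` writes deterministic single-frame CT series: ellipsoids of
distinct HU (defaults: a water "body", a 60 HU soft-tissue inclusion, a
700 HU bone inclusion) on an air background, stored as unsigned 16-bit
with slope 1 / intercept −1024 (so HU conversion is non-trivial), optional
seeded Gaussian noise (default σ = 5 HU, a typical quantum-noise
magnitude), and optional attribute defects for validation tests. The
default geometry — 64×64 pixels × 40 slices, 0.5 mm pixels, 1.0 mm slice
spacing — makes z-resampling interpolate genuinely new planes (79 output
planes from 40 inputs) while a full seal→tamper→verify cycle stays under a
second.

Phantoms emulate the *geometry and encoding* of CT series, not anatomy:
no partial-volume texture, no scanner artefacts, no compressed transfer
syntaxes, no multi-frame objects. Passing tests therefore demonstrate the
scheme's detection logic and bit-reproducibility, not its behaviour on the
full variability of clinical data.

## Adversary model

Tamper operations are pure functions on the sorted slice list,
deterministic given their seed: insert (duplicate keeps its SOP UID;
foreign slices come from another series), delete, and modify (n chosen
pixels shifted by exactly ±amplitude HU in stored units; signs i.i.d. per
pixel, or all-positive to guarantee non-cancellation). Stored values are
clipped to the pixel dtype, so a negative shift on an air pixel (stored 0)
saturates — the exact-shift guarantee holds wherever no clipping occurs.

## Known limitations

- **Whole-dataset replacement.** If dataset *and* manifest are replaced
  consistently, verification passes; the seal binds content to the
  manifest, not to a provenance anchor. Binding the manifest to an
  out-of-band channel (or signing it) is orthogonal and out of scope.
- **Bit-identical duplicate insertion.** A duplicated slice carries its
  original slice location; location-based interpolation provably yields
  the identical volume, so RMSE and all histograms stay zero. Detection
  of this attack rests on the duplicate-UID validation finding and the
  manifest's image-count check, both of which fail the verdict.
- **Ray-mean cancellation.** Modifications of opposite sign within one
  projection ray can cancel in the mean (e.g. +10 and −10 HU in the same
  column of one slice); the all-positive mode exists precisely to exclude
  this in soundness tests.
- **Sampling blind spots.** A slice inserted strictly between two output
  sample planes influences no sample when slice spacing equals pixel
  spacing; the image-count check covers this, and the default phantom's
  2:1 spacing ratio keeps interpolation sensitive in tests.
- **Boundary deletions.** Deleting the first or last slice shrinks the
  DRR, which is reported as a shape mismatch (FAIL with reason) rather
  than a nonzero RMSE.
- No protection of non-image objects (RT Plan/Dose/Structure), no DICOM
  networking, no multi-frame objects, and no constant-time cryptography.
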