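# drrseal

Tamper-evident sealing and verification of radiology image series.

When a CT (or similar volumetric) series is sent across an insecure
network, an adversary can insert an image, delete one, or nudge pixel
intensities — edits that are invisible to per-file checks and hard to spot
by eye. `drrseal` protects the *dataset as a whole*: it derives a single 2D
fingerprint image from the full 3D volume, encrypts it block-by-block, and
lets the receiver regenerate the same fingerprint from the transmitted
files and compare. Any change anywhere in the series perturbs the
fingerprint.

It is aimed at PACS/radiation-oncology tooling developers and medical-image
researchers who need a dataset-level integrity check that works on plain
single-frame DICOM files, with no network infrastructure required — a
synthetic CT phantom generator is included so the entire pipeline runs
self-contained.

## Method

1. **Validate and stack.** The series is checked for DICOM attribute
   requirements (type 1 / type 2 / type 1c) and duplicate SOP Instance
   UIDs, sorted by Slice Location (0020,1041), converted to Hounsfield
   units via `HU = stored · slope + intercept`, and resampled along z by
   linear interpolation into an isotropic volume `V[z][y][x]` (voxel edge =
   in-plane pixel spacing).
2. **Project.** The digitally reconstructed radiograph (DRR) is the mean
   projection along one axis, e.g. coronal:
   `DRR[z][x] = (1/n_y) Σ_y V[z][y][x]`. Axial and sagittal projections are
   supported the same way.
3. **Seal.** The DRR is cut into a 4×4 grid of equal blocks (8×8 optional)
   visited in JPEG-style zig-zag order `1, 2, 5, 9, 6, 3, …`, and each
   serialized block is encrypted independently with AES-256-CBC (PKCS#7,
   fresh random IV per block) under a key derived from a passphrase with
   salted PBKDF2-HMAC-SHA256. Ciphertexts and all comparison parameters go
   into a JSON sidecar, the *sealed manifest*.
4. **Verify.** The receiver decrypts the blocks, regenerates the DRR from
   the received files with the identical pipeline, and compares: per block,
   the L1 distance between integer-HU histograms (bins −1024…+3072); and
   globally, `RMSE = sqrt(mean((DRR₁ − DRR₂)²))`. Both pipelines are
   bit-reproducible, so an unmodified series yields **exactly** zero on
   both metrics; any nonzero value means the dataset was modified. Duplicate
   UIDs, a changed file count, or validation findings also fail the verdict.

## Worked example

Everything below runs offline on a generated phantom (64×64 pixels × 40
slices; ellipsoids of water, soft tissue and bone on an air background):

```sh
export DRRSEAL_PASSPHRASE=correct-horse
drrseal phantom --out demo/series
drrseal seal   --input demo/series --out demo/series.seal.json
drrseal verify --input demo/series --manifest demo/series.seal.json
```

```
PASS: rmse=0.0 hist_diff_total=0
```

The untouched series verifies with RMSE exactly `0.0` and zero total
histogram difference over all 16 blocks — the sealed fingerprint and the
regenerated one are bit-identical. Now modify 100 pixels of one slice by
+10 HU (the classic subtle pixel attack) and verify again:

```sh
drrseal tamper --input demo/series --out demo/tampered \
        --op modify --index 20 --n-pixels 100 --all-positive
drrseal verify --input demo/tampered --manifest demo/series.seal.json
```

```
FAIL: rmse=0.04678335768360736 hist_diff_total=52
```

A hundred +10 HU pixels in *one* slice of forty shift each affected
projection ray's mean by a fraction of an HU, yet the verdict flips to
FAIL (exit code 2): the RMSE is small but strictly positive, and 52
histogram counts moved across bins. Insertions and deletions are detected
the same way (`--op insert|delete`), and `drrseal bench` runs the whole
untampered + tampered grid and writes a CSV.

From Python the same cycle is:

```python
from drrseal import PhantomSpec, generate_phantom, seal_series, verify

generate_phantom(PhantomSpec(), "demo/series")
manifest = seal_series("demo/series", "correct-horse")
report = verify("demo/series", manifest, "correct-horse")
print(report.verdict, report.rmse)   # PASS 0.0
```

## Limitations

- If the entire dataset *and* the sealed manifest are replaced together,
  verification cannot notice — the seal binds content, not provenance.
- A bit-identical duplicated slice at its own slice location does not
  change the location-interpolated volume; it is caught by the
  duplicate-UID and image-count checks rather than by the DRR metrics.
- Opposite-signed modifications within one projection ray can cancel in
  the mean. See `docs/methods.md` for the full discussion.
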