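import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drrseal import (
    DEFAULT_RULES,
    DegenerateSeriesError,
    EmptySeriesError,
    GeometryMismatchError,
    PhantomSpec,
    SliceImage,
    UnsortableSeriesError,
    ValidationRule,
    build_volume,
    generate_phantom,
    read_series,
    sort_slices,
    to_hu,
    validate_series,
)
from drrseal.phantom import Defect
from pydicom.dataset import Dataset


def make_slice(loc=None, inst=None, uid="uid", rows=4, cols=4, pixels=None,
               slope=1.0, intercept=-1024.0, spacing=(1.0, 1.0)):
    if pixels is None:
        pixels = np.zeros((rows, cols), dtype=np.uint16)
    ds = Dataset()
    ds.SOPInstanceUID = uid
    return SliceImage(
        sop_instance_uid=uid, slice_location=loc, instance_number=inst,
        rows=pixels.shape[0], cols=pixels.shape[1], stored_pixels=pixels,
        rescale_slope=slope, rescale_intercept=intercept,
        pixel_spacing=spacing, attributes=ds,
    )


# ------------------------------------------------------------- read_series

class TestReadSeries:
    def test_reads_one_slice_per_file(self, small_series_dir, small_spec):
        assert len(read_series(small_series_dir)) == small_spec.n_slices

    def test_skips_non_dicom_with_warning(self, tmp_path, caplog):
        generate_phantom(PhantomSpec(rows=8, cols=8, n_slices=3, noise_sigma=0), tmp_path)
        (tmp_path / "notes.txt").write_text("not dicom")
        with caplog.at_level("WARNING"):
            slices = read_series(tmp_path)
        assert len(slices) == 3
        assert any("notes.txt" in r.message for r in caplog.records)

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(EmptySeriesError):
            read_series(tmp_path)


# --------------------------------------------------------------- validation

class TestValidateSeries:
    def test_clean_phantom_is_valid(self, small_slices):
        report = validate_series(small_slices)
        assert report.is_valid
        assert report.per_slice_findings == [] and report.duplicate_uids == []

    def test_missing_pixel_data_is_type1_finding(self, tmp_path):
        spec = PhantomSpec(rows=8, cols=8, n_slices=3, noise_sigma=0,
                           defects=[Defect(slice_index=1, tag="PixelData", action="drop")])
        generate_phantom(spec, tmp_path)
        report = validate_series(read_series(tmp_path))
        t1 = [f for f in report.per_slice_findings if f.type_class == "type1"]
        assert len(t1) == 1
        assert t1[0].tag == "PixelData" and t1[0].failure_kind == "missing_tag"
        assert not report.is_valid

    def test_empty_type2_value_is_not_a_finding(self, tmp_path):
        spec = PhantomSpec(rows=8, cols=8, n_slices=3, noise_sigma=0,
                           defects=[Defect(slice_index=0, tag="PatientName", action="empty")])
        generate_phantom(spec, tmp_path)
        report = validate_series(read_series(tmp_path))
        assert report.is_valid

    def test_empty_type1_value_is_a_finding(self):
        s = make_slice()
        s.attributes.Modality = ""
        rule = ValidationRule("Modality", "Modality", "type1")
        report = validate_series([s], [rule])
        assert [f.failure_kind for f in report.per_slice_findings] == ["empty_value"]

    def test_duplicate_uids_reported(self, small_slices):
        report = validate_series(list(small_slices) + [small_slices[2]])
        assert report.duplicate_uids == [small_slices[2].sop_instance_uid]
        assert not report.is_valid

    def test_type1c_requires_conditioned_tag_only_when_condition_set(self):
        rule = ValidationRule("SliceLocation", "Slice Location", "type1c",
                              condition_tag="ImagePositionPatient")
        s = make_slice(loc=None)
        assert validate_series([s], [rule]).is_valid  # condition absent
        s.attributes.ImagePositionPatient = ["0", "0", "1"]
        report = validate_series([s], [rule])
        assert [f.failure_kind for f in report.per_slice_findings] == ["condition_unmet"]


# ------------------------------------------------------------------ sorting

class TestSortSlices:
    def test_sorts_by_location(self):
        slices = [make_slice(loc=l, uid=f"u{i}") for i, l in enumerate([10.0, -5.0, 2.5])]
        assert [s.slice_location for s in sort_slices(slices)] == [-5.0, 2.5, 10.0]

    def test_tie_broken_by_instance_number(self):
        a = make_slice(loc=0.0, inst=2, uid="a")
        b = make_slice(loc=0.0, inst=1, uid="b")
        assert [s.instance_number for s in sort_slices([a, b])] == [1, 2]

    def test_instance_number_fallback(self):
        slices = [make_slice(inst=i, uid=f"u{i}") for i in (3, 1, 2)]
        assert [s.instance_number for s in sort_slices(slices)] == [1, 2, 3]

    def test_unsortable_series(self):
        with pytest.raises(UnsortableSeriesError):
            sort_slices([make_slice(loc=1.0, uid="a"), make_slice(uid="b")])

    @given(st.permutations(list(range(8))))
    def test_sort_is_a_permutation(self, order):
        slices = [make_slice(loc=float(l), uid=f"u{l}") for l in order]
        out = sort_slices(slices)
        assert sorted(s.sop_instance_uid for s in out) == sorted(s.sop_instance_uid for s in slices)
        assert [s.slice_location for s in out] == sorted(float(l) for l in order)


# ------------------------------------------------------------------- to_hu

class TestToHu:
    @pytest.mark.parametrize(
        "stored,slope,intercept,expected",
        [(0, 1.0, -1024.0, -1024.0), (2048, 1.0, -1024.0, 1024.0), (100, 2.0, 0.0, 200.0)],
    )
    def test_affine_examples(self, stored, slope, intercept, expected):
        s = make_slice(pixels=np.full((2, 2), stored, dtype=np.uint16),
                       slope=slope, intercept=intercept)
        assert np.all(to_hu(s) == expected)

    def test_matches_scalar_loop_oracle(self, rng):
        pixels = rng.integers(0, 4096, size=(8, 8)).astype(np.uint16)
        s = make_slice(pixels=pixels, slope=1.5, intercept=-1000.0)
        hu = to_hu(s)
        for i in range(8):
            for j in range(8):
                assert hu[i, j] == pixels[i, j] * 1.5 + -1000.0


# ------------------------------------------------------------- build_volume

def series_from_planes(planes, locations, spacing=1.0):
    return [
        make_slice(loc=float(loc), inst=i, uid=f"u{i}",
                   pixels=(plane + 1024).astype(np.uint16),
                   spacing=(spacing, spacing))
        for i, (plane, loc) in enumerate(zip(planes, locations))
    ]


class TestBuildVolume:
    def test_midpoint_interpolation(self):
        planes = [np.zeros((4, 4)), np.full((4, 4), 100.0)]
        vol = build_volume(series_from_planes(planes, [0.0, 1.0], spacing=0.5))
        assert vol.hu.shape == (3, 4, 4)
        assert np.all(vol.hu[0] == 0.0)
        assert np.all(vol.hu[1] == 50.0)
        assert np.all(vol.hu[2] == 100.0)

    def test_isotropic_input_is_identity(self, rng):
        planes = [rng.integers(-1024, 3072, size=(6, 6)).astype(float) for _ in range(5)]
        vol = build_volume(series_from_planes(planes, [0.0, 1.0, 2.0, 3.0, 4.0]))
        assert vol.hu.shape == (5, 6, 6)
        for k in range(5):
            np.testing.assert_array_equal(vol.hu[k], planes[k])

    def test_output_plane_count_matches_position_enumeration(self):
        # Independent oracle: enumerate z0 + k*spacing while <= z_last.
        spacing, n, st_mm = 0.5, 40, 1.0
        locations = [i * st_mm for i in range(n)]
        k, expected = 0, 0
        while locations[0] + k * spacing <= locations[-1] + 1e-9:
            expected += 1
            k += 1
        planes = [np.zeros((4, 4))] * n
        vol = build_volume(series_from_planes(planes, locations, spacing=spacing))
        assert vol.hu.shape[0] == expected == 79

    def test_non_uniform_spacing_supported(self):
        planes = [np.zeros((4, 4)), np.full((4, 4), 30.0), np.full((4, 4), 90.0)]
        vol = build_volume(series_from_planes(planes, [0.0, 3.0, 4.0], spacing=1.0))
        assert vol.hu.shape[0] == 5
        assert np.allclose(vol.hu[1], 10.0) and np.allclose(vol.hu[2], 20.0)
        assert np.allclose(vol.hu[3], 30.0) and np.allclose(vol.hu[4], 90.0)

    def test_geometry_mismatch_errors(self):
        a = make_slice(loc=0.0, uid="a")
        b = make_slice(loc=1.0, uid="b", pixels=np.zeros((5, 4), dtype=np.uint16))
        with pytest.raises(GeometryMismatchError):
            build_volume([a, b])
        c = make_slice(loc=1.0, uid="c", spacing=(2.0, 1.0))
        with pytest.raises(GeometryMismatchError):
            build_volume([a, c])

    def test_degenerate_all_locations_equal(self):
        slices = [make_slice(loc=5.0, uid="a"), make_slice(loc=5.0, uid="b")]
        with pytest.raises(DegenerateSeriesError):
            build_volume(slices)

    def test_provenance_and_metadata(self, small_slices, small_spec):
        vol = build_volume(small_slices)
        assert vol.n_slices_original == small_spec.n_slices
        assert vol.provenance == [s.sop_instance_uid for s in small_slices]
        assert vol.spacing == small_spec.pixel_spacing

    @given(st.integers(0, 2**31 - 1))
    def test_interpolated_planes_bounded_by_bracketing_slices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        locs = np.cumsum(rng.uniform(0.5, 3.0, size=n)) + 10.0
        planes = [rng.integers(-1024, 3072, size=(3, 3)).astype(float) for _ in range(n)]
        vol = build_volume(series_from_planes(planes, locs.tolist(), spacing=0.7))
        stack = np.array(planes)
        for k in range(vol.hu.shape[0]):
            z = locs[0] + k * 0.7
            j = int(np.searchsorted(locs, z + 1e-12)) - 1
            j = min(max(j, 0), n - 2)
            lo = np.minimum(stack[j], stack[j + 1])
            hi = np.maximum(stack[j], stack[j + 1])
            assert np.all(vol.hu[k] >= lo - 1e-9) and np.all(vol.hu[k] <= hi + 1e-9)
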