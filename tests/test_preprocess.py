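"""Ingestion, resampling, windowing, multi-scale cropping and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcseg import (CTVolume, GTVMask, CropSample, augment, canonical_scales,
                    crop_multiscale, load_volume, resample_to_spacing,
                    window_and_normalize)
from npcseg.volume import save_nifti


# ---- ingestion -----------------------------------------------------------

def test_nifti_round_trip_preserves_voxels_and_spacing(tmp_path):
    rng = np.random.default_rng(0)
    voxels = rng.uniform(-1000, 1000, size=(5, 8, 9)).round(3)
    save_nifti(tmp_path / "v.nii.gz", voxels, (3.0, 0.9, 0.9))
    vol = load_volume(tmp_path / "v.nii.gz")
    assert np.allclose(vol.voxels, voxels)
    assert vol.spacing_mm == pytest.approx((3.0, 0.9, 0.9))


def _write_dicom_slice(path, rows, cols, z, pixel_spacing=0.8, thickness=3.0,
                       orientation=(1, 0, 0, 0, 1, 0)):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.PatientID = "synthetic"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [pixel_spacing, pixel_spacing]
    ds.SliceThickness = thickness
    ds.ImagePositionPatient = [0.0, 0.0, z]
    ds.ImageOrientationPatient = list(orientation)
    ds.InstanceNumber = int(z / thickness)
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.SamplesPerPixel, ds.PhotometricInterpretation = 1, "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit, ds.PixelRepresentation = 15, 0
    arr = np.full((rows, cols), 1024 + int(z), dtype=np.uint16)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def test_dicom_series_header_echo(tmp_path):
    for z in (0.0, 3.0, 6.0):
        _write_dicom_slice(tmp_path / f"s{int(z)}.dcm", 16, 16, z)
    vol = load_volume(tmp_path, format="dicom-series")
    assert vol.shape == (3, 16, 16)
    assert vol.spacing_mm == pytest.approx((3.0, 0.8, 0.8))
    # rescale applied: stored 1024+z with intercept -1024 -> HU == z
    assert np.allclose(vol.voxels[1], 3.0)


def test_dicom_series_with_mismatched_slice_shape_errors(tmp_path):
    _write_dicom_slice(tmp_path / "a.dcm", 16, 16, 0.0)
    _write_dicom_slice(tmp_path / "b.dcm", 16, 12, 3.0)
    with pytest.raises(ValueError, match="mismatched"):
        load_volume(tmp_path, format="dicom-series")


# ---- resampling ----------------------------------------------------------

def test_resample_identity_when_already_at_target():
    vol = CTVolume(np.zeros((4, 10, 10)), (3.0, 1.0, 1.0))
    out, _ = resample_to_spacing(vol)
    assert np.array_equal(out.voxels, vol.voxels)


def test_resample_scale_arithmetic_and_binary_mask():
    rng = np.random.default_rng(1)
    vol = CTVolume(rng.uniform(-100, 100, (4, 50, 50)), (3.0, 2.0, 2.0))
    mask = GTVMask((rng.random((4, 50, 50)) > 0.7).astype(np.uint8), (3.0, 2.0, 2.0))
    out_vol, out_mask = resample_to_spacing(vol, mask)
    assert out_vol.shape == (4, 100, 100)
    assert set(np.unique(out_mask.voxels)) <= {0, 1}
    assert out_vol.spacing_mm == (3.0, 1.0, 1.0)


def test_resample_rejects_bad_spacing():
    with pytest.raises(ValueError):
        CTVolume(np.zeros((4, 8, 8)), (0.0, 1.0, 1.0))


# ---- windowing -----------------------------------------------------------

@pytest.mark.parametrize("hu,expected", [
    (-150.0, 0.0),      # window floor
    (500.0, 1.0),       # window ceiling
    (175.0, 0.5),       # midpoint of the 650-HU window
    (3071.0, 0.0),      # above the window: blanked
    (-1024.0, 0.0),     # below the window: blanked
])
def test_window_and_normalize_mapping(hu, expected):
    vol = CTVolume(np.full((1, 8, 8), hu), (3.0, 1.0, 1.0))
    out = window_and_normalize(vol)
    assert out.voxels[0, 0, 0] == pytest.approx(expected)


def test_window_rejects_inverted_bounds():
    vol = CTVolume(np.zeros((1, 8, 8)), (3.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        window_and_normalize(vol, low=10.0, high=-10.0)


def test_normalization_idempotent_with_matching_window():
    rng = np.random.default_rng(2)
    vol = CTVolume(rng.uniform(0, 1, (2, 8, 8)), (3.0, 1.0, 1.0))
    once = window_and_normalize(vol, low=0.0, high=1.0)
    twice = window_and_normalize(
        CTVolume(once.voxels, once.spacing_mm), low=0.0, high=1.0)
    assert np.allclose(once.voxels, twice.voxels)


# ---- scales and cropping -------------------------------------------------

def test_canonical_scales_fractions_and_order():
    scales = canonical_scales()
    assert [s.name for s in scales] == ["extra-small", "small", "medium",
                                        "large", "extra-large"]
    assert [s.xy_fraction for s in scales] == [0.40, 0.55, 0.70, 0.85, 1.00]
    assert [s.z_fraction for s in scales] == [0.50, 0.60, 0.70, 0.80, 0.90]


def test_crop_sizes_follow_floor_rule(normalized_volume, gtv_mask, rng):
    medium = canonical_scales()[2]
    sample = crop_multiscale(normalized_volume, gtv_mask, medium, rng)
    d, h, w = normalized_volume.shape
    assert sample.image.shape == (int(0.7 * d), int(0.7 * h), int(0.7 * w))
    assert sample.label.shape == sample.image.shape


def test_crop_sizes_monotone_across_scales(normalized_volume, gtv_mask, rng):
    shapes = [crop_multiscale(normalized_volume, gtv_mask, s, rng).image.shape
              for s in canonical_scales()]
    for smaller, larger in zip(shapes, shapes[1:]):
        assert all(a <= b for a, b in zip(smaller, larger))


def test_crop_window_contains_gtv_centroid(normalized_volume, gtv_mask):
    from scipy import ndimage
    centroid = tuple(int(round(c)) for c in
                     ndimage.center_of_mass(gtv_mask.voxels))
    for seed in range(10):
        rng = np.random.default_rng(seed)
        s = crop_multiscale(normalized_volume, gtv_mask,
                            canonical_scales()[0], rng)
        for c, o, size in zip(centroid, s.offset, s.image.shape):
            assert o <= c < o + size


def test_crop_with_empty_mask_falls_back_to_uniform(normalized_volume, caplog):
    empty = GTVMask(np.zeros(normalized_volume.shape, dtype=np.uint8),
                    normalized_volume.spacing_mm)
    with caplog.at_level("WARNING"):
        sample = crop_multiscale(normalized_volume, empty,
                                 canonical_scales()[2],
                                 np.random.default_rng(0))
    assert sample.label.sum() == 0
    assert "empty" in caplog.text.lower()


# ---- augmentation --------------------------------------------------------

def _fixed_sample(rng):
    img = rng.random((6, 10, 10))
    lab = (rng.random((6, 10, 10)) > 0.8).astype(np.uint8)
    return CropSample(img, lab, canonical_scales()[2])


def test_augment_identity_when_no_transform_fires(rng):
    sample = _fixed_sample(rng)
    # find a seed whose four Bernoulli draws all miss
    for seed in range(200):
        r = np.random.default_rng(seed)
        if all(np.random.default_rng(seed).random(4) >= 0.5):
            out = augment(sample, r)
            assert np.array_equal(out.image, sample.image)
            assert np.array_equal(out.label, sample.label)
            return
    pytest.fail("no identity seed found in 200 tries")


def test_flip_is_an_involution(rng):
    sample = _fixed_sample(rng)
    flipped = np.flip(sample.image, axis=1)
    assert np.array_equal(np.flip(flipped, axis=1), sample.image)


@given(seed=st.integers(0, 500))
@settings(max_examples=30, deadline=None)
def test_augment_preserves_mask_count_without_crop(seed):
    """Flip/rotation/transposition are permutations: voxel counts invariant."""
    base = np.random.default_rng(99)
    sample = _fixed_sample(base)
    r = np.random.default_rng(seed)
    draws = np.random.default_rng(seed).random(4)
    out = augment(sample, r)
    if draws[3] >= 0.5:  # no sub-crop fired: pure permutation ops
        assert out.label.sum() == sample.label.sum()
        assert out.image.sum() == pytest.approx(sample.image.sum())


def test_augment_keeps_label_binary(rng):
    for seed in range(10):
        out = augment(_fixed_sample(rng), np.random.default_rng(seed))
        assert set(np.unique(out.label)) <= {0, 1}
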