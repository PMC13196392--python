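"""Ingestion, eligibility rules and the two preprocessing paths."""

import datetime as dt
import json

import numpy as np
import pytest

from osteoscreen.imgprep import (
    DXA_GAP_GT_6M,
    LT_2_VERTEBRAE,
    SPACING_GT_0_2,
    Radiograph,
    SpacingMissingError,
    check_eligibility,
    load_radiograph,
    prepare_classification_roi,
    prepare_segmentation_input,
)
from osteoscreen.labels import DXARecord
from osteoscreen.pipeline import sample_to_radiograph
from osteoscreen.segment import assign_vertebra_levels, truth_instance_set


def _rg(spacing=0.143, date=dt.date(2023, 6, 15)):
    return Radiograph(
        pixels=np.zeros((64, 64), dtype=np.uint16),
        pixel_spacing_mm=(spacing, spacing),
        acquisition_date=date,
    )


def _dxa(gap_days=0):
    return DXARecord(
        bmd_t_score=-1.0, tbs=1.3, acquisition_date=dt.date(2023, 6, 15) + dt.timedelta(days=gap_days)
    )


class TestLoading:
    def test_sidecar_round_trip(self, tmp_path, one_phantom):
        from osteoscreen.phantom import write_phantom

        paths = write_phantom(one_phantom, tmp_path)
        rg = load_radiograph(paths["image"])
        assert rg.pixel_spacing_mm == (0.143, 0.143)
        assert rg.age_years == one_phantom.age_years

    def test_missing_sidecar_is_spacing_error(self, tmp_path):
        import imageio.v3 as iio

        p = tmp_path / "img.png"
        iio.imwrite(p, np.zeros((16, 16), dtype=np.uint16))
        with pytest.raises(SpacingMissingError):
            load_radiograph(p)

    def test_sidecar_without_age_keeps_missing(self, tmp_path):
        import imageio.v3 as iio

        p = tmp_path / "img.png"
        iio.imwrite(p, np.zeros((16, 16), dtype=np.uint16))
        (tmp_path / "img.json").write_text(json.dumps({"pixel_spacing_mm": 0.15}))
        rg = load_radiograph(p)
        assert rg.age_years is None
        assert rg.sex is None

    def test_dicom_missing_spacing_errors(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileMetaDataset

        ds = pydicom.Dataset()
        ds.PatientID = "X"
        ds.Rows, ds.Columns = 8, 8
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.zeros((8, 8), dtype=np.uint16).tobytes()
        meta = FileMetaDataset()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(entropy_srcs=["fixture"])
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.file_meta = meta
        p = tmp_path / "img.dcm"
        ds.save_as(p, enforce_file_format=True)
        with pytest.raises(SpacingMissingError):
            load_radiograph(p)


class TestEligibility:
    def test_coarse_spacing_excluded(self):
        res = check_eligibility(_rg(spacing=0.25), _dxa(), 4)
        assert res.reasons == [SPACING_GT_0_2]

    def test_dxa_gap_over_six_months_excluded(self):
        res = check_eligibility(_rg(), _dxa(gap_days=200), 4)
        assert res.reasons == [DXA_GAP_GT_6M]
        assert check_eligibility(_rg(), _dxa(gap_days=183), 4).eligible

    def test_all_rules_satisfied(self):
        res = check_eligibility(_rg(), _dxa(gap_days=30), 3)
        assert res.eligible and res.reasons == []

    def test_vertebra_rule_deferred_when_unknown(self):
        assert check_eligibility(_rg(), _dxa(), None).eligible
        assert check_eligibility(_rg(), _dxa(), 1).reasons == [LT_2_VERTEBRAE]

    def test_eligibility_monotone(self):
        """Removing one violation never introduces another reason code."""
        full = set(check_eligibility(_rg(0.25), _dxa(gap_days=400), 1).reasons)
        fewer = set(check_eligibility(_rg(0.143), _dxa(gap_days=400), 1).reasons)
        assert fewer <= full


class TestSegmentationInput:
    def test_constant_image_maps_to_mid_grey(self):
        rg = Radiograph(pixels=np.full((100, 80), 500, np.uint16), pixel_spacing_mm=(0.1, 0.1))
        img8, _ = prepare_segmentation_input(rg)
        assert img8.shape == (1024, 1024)
        content = img8[img8 > 0]
        assert np.all(content == 128)

    def test_aspect_preserving_resize_and_padding(self):
        rg = Radiograph(pixels=np.random.default_rng(0).integers(0, 1000, (2048, 1536)).astype(np.uint16),
                        pixel_spacing_mm=(0.1, 0.1))
        img8, scale = prepare_segmentation_input(rg)
        assert scale.content_shape == (1024, 768)
        assert scale.pad_left == (1024 - 768) // 2

    def test_mask_round_trip_recovers_bbox_within_one_px(self, one_phantom):
        rg = sample_to_radiograph(one_phantom)
        _, scale = prepare_segmentation_input(rg)
        mask = one_phantom.masks["L2"]
        rows, cols = np.nonzero(mask)
        # forward: native mask -> 1024 grid; backward via the scale record
        from skimage.transform import resize

        content = resize(mask.astype(float), scale.content_shape, order=0) > 0.5
        grid = np.zeros((1024, 1024), bool)
        grid[scale.pad_top : scale.pad_top + scale.content_shape[0],
             scale.pad_left : scale.pad_left + scale.content_shape[1]] = content
        back = scale.mask_to_native(grid)
        r2, c2 = np.nonzero(back)
        assert abs(rows.min() - r2.min()) <= 1 and abs(rows.max() - r2.max()) <= 1
        assert abs(cols.min() - c2.min()) <= 1 and abs(cols.max() - c2.max()) <= 1

    def test_resampling_preserves_physical_extent(self, one_phantom):
        rg = sample_to_radiograph(one_phantom)
        img8, scale = prepare_segmentation_input(rg)
        native_h_mm = rg.pixels.shape[0] * rg.pixel_spacing_mm[0]
        content_spacing = rg.pixel_spacing_mm[0] / scale.scale
        assert scale.content_shape[0] * content_spacing == pytest.approx(native_h_mm, abs=content_spacing)


class TestClassificationRoi:
    def test_resample_ratio(self, one_phantom):
        rg = sample_to_radiograph(one_phantom)
        instances = assign_vertebra_levels(truth_instance_set(one_phantom))
        roi, rec = prepare_classification_roi(rg, instances)
        r0, r1, c0, c1 = rec.native_box
        assert roi.shape[0] == pytest.approx((r1 - r0) * 0.143 / 0.2, abs=1)
        assert roi.min() >= 0.0 and roi.max() <= 1.0

    def test_roi_contains_every_vertebra_pixel(self, one_phantom):
        rg = sample_to_radiograph(one_phantom)
        instances = assign_vertebra_levels(truth_instance_set(one_phantom))
        _, rec = prepare_classification_roi(rg, instances)
        r0, r1, c0, c1 = rec.native_box
        union = np.zeros(rg.pixels.shape, bool)
        for inst in instances.instances:
            if inst.cls == "vertebra":
                union |= inst.mask
        rows, cols = np.nonzero(union)
        assert r0 <= rows.min() and rows.max() < r1
        assert c0 <= cols.min() and cols.max() < c1

    def test_constant_roi_stays_constant(self):
        rg = Radiograph(pixels=np.full((200, 100), 7000, np.uint16), pixel_spacing_mm=(0.2, 0.2))
        from osteoscreen.segment import Instance, InstanceSet

        m1 = np.zeros((200, 100), bool)
        m1[10:60, 20:80] = True
        m2 = np.zeros((200, 100), bool)
        m2[80:130, 20:80] = True
        inst = InstanceSet([Instance("vertebra", m1, 1.0, "L1"), Instance("vertebra", m2, 1.0, "L2")])
        roi, _ = prepare_classification_roi(rg, inst)
        assert np.unique(roi).size == 1

    def test_fewer_than_two_vertebrae_rejected(self, one_phantom):
        from osteoscreen.segment import Instance, InstanceSet

        rg = sample_to_radiograph(one_phantom)
        only_one = InstanceSet([Instance("vertebra", one_phantom.masks["L1"], 1.0, "L1")])
        with pytest.raises(ValueError):
            prepare_classification_roi(rg, only_one)
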