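import numpy as np
import pytest

from choroquant.errors import DetectionError, FlatteningError, ValidationError
from choroquant.scan_model import BScan
from choroquant.segmentation import (
    BoundaryCurve,
    BoundaryKind,
    detect_rpe,
    flatten,
    segment_choroid,
    use_external_boundaries,
)


def flat_band_image(h=64, w=48, row=30, thickness=4, level=200, base=10):
    img = np.full((h, w), base, dtype=np.uint8)
    img[row: row + thickness, :] = level
    return BScan(image=img, angle_deg=0.0)


class TestDetectRpe:
    def test_constant_band_gives_constant_curve(self):
        curve = detect_rpe(flat_band_image(row=30, thickness=4))
        assert curve.kind is BoundaryKind.RPE
        assert np.all(np.abs(curve.rows - 31.5) <= 1.0)  # band center 30..33

    def test_all_zero_image_fails(self):
        with pytest.raises(DetectionError):
            detect_rpe(BScan(image=np.zeros((32, 16), dtype=np.uint8), angle_deg=0.0))

    def test_noiseless_phantom_rpe_within_one_pixel(self, small_phantom_noiseless):
        scan_set, truth = small_phantom_noiseless
        for k, bscan in enumerate(scan_set.bscans):
            curve = detect_rpe(bscan)
            assert np.mean(np.abs(curve.rows - truth.rpe_rows[k])) <= 1.0


class TestFlatten:
    def test_already_flat_is_identity(self):
        bscan = flat_band_image()
        rpe = detect_rpe(bscan)
        flat, shift = flatten(bscan, rpe)
        assert np.array_equal(flat.image, bscan.image)
        assert np.all(shift == 0)

    def test_tilted_phantom_rpe_constant_after_flatten(self, small_phantom_noiseless):
        scan_set, _ = small_phantom_noiseless
        for bscan in scan_set.bscans[:3]:
            rpe = detect_rpe(bscan)
            flat, _ = flatten(bscan, rpe)
            rpe2 = detect_rpe(flat)
            assert np.ptp(rpe2.rows) <= 2.0  # constant to within ±1 px

    def test_idempotence(self, small_phantom_noiseless):
        scan_set, _ = small_phantom_noiseless
        bscan = scan_set.bscans[0]
        flat, _ = flatten(bscan, detect_rpe(bscan))
        flat2, shift2 = flatten(flat, detect_rpe(flat))
        assert np.array_equal(flat.image, flat2.image)
        assert np.all(shift2 == 0)

    def test_column_intensity_multiset_preserved(self, small_phantom):
        """Flattening is shift-only: per-column nonzero intensities survive
        (up to pixels shifted out of frame)."""
        scan_set, _ = small_phantom
        bscan = scan_set.bscans[1]
        rpe = detect_rpe(bscan)
        flat, shift = flatten(bscan, rpe)
        h = bscan.image.shape[0]
        for c in (0, 50, 200):
            src = bscan.image[:, c]
            dst = flat.image[:, c]
            s = shift[c]
            kept = src[max(0, -s): h - s if s > 0 else h]
            assert sorted(dst[dst > 0]) == sorted(kept[kept > 0])

    def test_excessive_shift_raises(self):
        # a steep (but continuity-legal) ramp forces |shift| > h/2 at the ends
        bscan = flat_band_image(h=32, row=10, thickness=4)
        ramp = np.linspace(0, 40, 48)
        with pytest.raises(FlatteningError):
            flatten(bscan, BoundaryCurve(ramp, BoundaryKind.RPE))


class TestSegmentChoroid:
    def test_noiseless_phantom_boundaries_within_two_px(self, small_phantom_noiseless):
        scan_set, truth = small_phantom_noiseless
        errs_u, errs_l = [], []
        for k, bscan in enumerate(scan_set.bscans):
            rpe = detect_rpe(bscan)
            flat, shift = flatten(bscan, rpe)
            seg = segment_choroid(flat, BoundaryCurve(rpe.rows + shift, BoundaryKind.RPE))
            errs_u.append(np.mean(np.abs(seg.upper.rows - (truth.upper_rows[k] + shift))))
            errs_l.append(np.mean(np.abs(seg.lower.rows - (truth.lower_rows[k] + shift))))
        assert np.mean(errs_u) <= 2.0
        assert np.mean(errs_l) <= 2.0

    def test_noisy_phantom_boundaries_within_four_px(self, small_phantom):
        scan_set, truth = small_phantom
        errs = []
        for k, bscan in enumerate(scan_set.bscans):
            rpe = detect_rpe(bscan)
            flat, shift = flatten(bscan, rpe)
            seg = segment_choroid(flat, BoundaryCurve(rpe.rows + shift, BoundaryKind.RPE))
            errs.append(np.mean(np.abs(seg.lower.rows - (truth.lower_rows[k] + shift))))
            errs.append(np.mean(np.abs(seg.upper.rows - (truth.upper_rows[k] + shift))))
        assert np.mean(errs) <= 4.0

    def test_determinism(self, small_phantom):
        scan_set, _ = small_phantom
        bscan = scan_set.bscans[0]
        rpe = detect_rpe(bscan)
        s1 = segment_choroid(bscan, rpe)
        s2 = segment_choroid(bscan, rpe)
        assert np.array_equal(s1.upper.rows, s2.upper.rows)
        assert np.array_equal(s1.lower.rows, s2.lower.rows)

    def test_band_ordering_invariants(self, small_phantom):
        scan_set, _ = small_phantom
        bscan = scan_set.bscans[2]
        rpe = detect_rpe(bscan)
        flat, shift = flatten(bscan, rpe)
        seg = segment_choroid(flat, BoundaryCurve(rpe.rows + shift, BoundaryKind.RPE))
        assert np.all(seg.upper.rows <= seg.lower.rows)
        assert np.all(seg.rpe.rows <= seg.upper.rows)


class TestExternalBoundaries:
    def test_pass_through_of_truth_curves(self, small_phantom):
        scan_set, truth = small_phantom
        k = 0
        seg = use_external_boundaries(
            scan_set.bscans[k],
            BoundaryCurve(truth.upper_rows[k].astype(float), BoundaryKind.CHOROID_UPPER),
            BoundaryCurve(truth.lower_rows[k].astype(float), BoundaryKind.CHOROID_LOWER),
        )
        assert np.array_equal(seg.upper.rows, truth.upper_rows[k])
        assert np.array_equal(seg.lower.rows, truth.lower_rows[k])
        assert np.array_equal(seg.rpe.rows, truth.upper_rows[k])

    def test_coincident_curves_accepted(self):
        bscan = flat_band_image()
        rows = np.full(48, 40.0)
        seg = use_external_boundaries(
            bscan,
            BoundaryCurve(rows, BoundaryKind.CHOROID_UPPER),
            BoundaryCurve(rows.copy(), BoundaryKind.CHOROID_LOWER),
        )
        assert np.array_equal(seg.upper.rows, seg.lower.rows)

    def test_crossing_curves_rejected(self):
        bscan = flat_band_image()
        up = np.full(48, 45.0)
        lo = np.full(48, 40.0)
        with pytest.raises(ValidationError):
            use_external_boundaries(
                bscan,
                BoundaryCurve(up, BoundaryKind.CHOROID_UPPER),
                BoundaryCurve(lo, BoundaryKind.CHOROID_LOWER),
            )

    def test_discontinuous_curve_rejected(self):
        rows = np.full(48, 30.0)
        rows[10] = 40.0
        with pytest.raises(ValidationError):
            BoundaryCurve(rows, BoundaryKind.CHOROID_UPPER)


class TestBoundaryCsv:
    def test_round_trip(self, small_phantom, tmp_path):
        from choroquant.segmentation import segmentation_from_csv, segmentation_to_csv

        scan_set, truth = small_phantom
        k = 0
        seg = use_external_boundaries(
            scan_set.bscans[k],
            BoundaryCurve(truth.upper_rows[k].astype(float), BoundaryKind.CHOROID_UPPER),
            BoundaryCurve(truth.lower_rows[k].astype(float), BoundaryKind.CHOROID_LOWER),
        )
        path = tmp_path / "b0.csv"
        segmentation_to_csv(seg, path)
        back = segmentation_from_csv(path)
        assert np.array_equal(back.upper.rows, seg.upper.rows)
        assert np.array_equal(back.lower.rows, seg.lower.rows)
        assert np.array_equal(back.rpe.rows, seg.rpe.rows)

    def test_empty_csv_rejected(self, tmp_path):
        from choroquant.segmentation import segmentation_from_csv

        p = tmp_path / "empty.csv"
        p.write_text("column_index,rpe_row,upper_row,lower_row\n")
        with pytest.raises(ValidationError):
            segmentation_from_csv(p)
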