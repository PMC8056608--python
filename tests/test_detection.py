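"""Detection: IoU geometry, PASCAL-style matching/AP with brute-force
oracles, the reference detector, and the 14-transform augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maps_hcm.detection import (
    TRANSFORM_IDS,
    augment_dataset,
    augment_image,
    average_precision,
    detect_cells,
    evaluate_detections,
    iou,
    match_detections,
    noise_sweep,
    precision_recall,
)
from maps_hcm.synthetic import SyntheticSpec, generate_dataset, generate_field
from maps_hcm.types import Annotation, BBox, Detection


def _iou_oracle(a: BBox, b: BBox) -> float:
    """Independent overlap computation from corner coordinates."""
    x0, x1 = max(a.left, b.left), min(a.left + a.width, b.left + b.width)
    y0, y1 = max(a.top, b.top), min(a.top + a.height, b.top + b.height)
    inter = max(x1 - x0, 0.0) * max(y1 - y0, 0.0)
    return inter / (a.width * a.height + b.width * b.height - inter)


class TestIoU:
    def test_self_overlap_is_one(self):
        b = BBox(0.1, 0.2, 0.3, 0.4)
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint_boxes_zero(self):
        assert iou(BBox(0.0, 0.0, 0.2, 0.2), BBox(0.5, 0.5, 0.2, 0.2)) == 0.0

    def test_hand_geometry_on_pixel_grid(self):
        """2x2 boxes at (0,0) and (1,1) on a 10x10 grid: 1/7."""
        a = BBox(0.0, 0.0, 0.2, 0.2)
        b = BBox(0.1, 0.1, 0.2, 0.2)
        assert iou(a, b) == pytest.approx(1 / 7)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def rand_box():
            l, t = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.05, 0.4, 2)
            return BBox(l, t, min(w, 1 - l), min(h, 1 - t))
        a, b = rand_box(), rand_box()
        assert iou(a, b) == pytest.approx(_iou_oracle(a, b))


class TestMatchDetections:
    def test_greedy_prefers_higher_score(self):
        truth = [BBox(0.1, 0.1, 0.2, 0.2)]
        preds = [
            Detection(BBox(0.1, 0.1, 0.2, 0.2), 0.9),
            Detection(BBox(0.12, 0.12, 0.2, 0.2), 0.95),
        ]
        flags, unmatched = match_detections(preds, truth, 0.5)
        # flags are in score order: the 0.95 detection matches first
        assert flags == [True, False] and unmatched == 0

    def test_no_predictions(self):
        flags, unmatched = match_detections([], [BBox(0, 0, 0.5, 0.5)] * 3, 0.5)
        assert flags == [] and unmatched == 3

    def test_agrees_with_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            truths = []
            for _ in range(rng.integers(1, 8)):
                l, t = rng.uniform(0, 0.7, 2)
                truths.append(BBox(l, t, rng.uniform(0.05, 0.25), rng.uniform(0.05, 0.25)))
            preds = []
            scores = rng.permutation(np.linspace(0.1, 0.99, 20))
            for s in scores:
                l, t = rng.uniform(0, 0.7, 2)
                preds.append(
                    Detection(BBox(l, t, rng.uniform(0.05, 0.25),
                                   rng.uniform(0.05, 0.25)), float(s))
                )
            flags, unmatched = match_detections(preds, truths, 0.3)
            # independent oracle: explicit sort + linear scans
            order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
            available = list(range(len(truths)))
            expected = []
            for i in order:
                ious = [(_iou_oracle(preds[i].bbox, truths[j]), j) for j in available]
                best = max(ious, default=(0.0, None))
                if best[0] >= 0.3:
                    available.remove(best[1])
                    expected.append(True)
                else:
                    expected.append(False)
            assert flags == expected
            assert unmatched == len(available)


class TestPrecisionRecallAP:
    def test_arithmetic(self):
        p, r = precision_recall([True] * 5 + [False], 6)
        assert p == pytest.approx(5 / 6) and r == pytest.approx(5 / 6)

    def test_perfect_detection(self):
        assert precision_recall([True, True], 2) == (1.0, 1.0)

    def test_no_detections_warns(self):
        with pytest.warns(UserWarning):
            assert precision_recall([], 5) == (0.0, 0.0)

    def test_single_true_positive_full_ap(self):
        assert average_precision([True], 1) == pytest.approx(1.0)

    def test_hand_envelope_example(self):
        """[TP, FP, TP] with 2 truths: 0.5*1 + 0.5*(2/3) = 0.8333."""
        assert average_precision([True, False, True], 2) == pytest.approx(5 / 6)

    def test_trailing_false_positives_leave_ap_unchanged(self):
        base = average_precision([True, True], 2)
        assert average_precision([True, True, False, False], 2) == pytest.approx(base)

    def test_ap_requires_ground_truth(self):
        with pytest.raises(ValueError):
            average_precision([True], 0)

    def test_matches_envelope_oracle_on_random_instances(self):
        """AP equals a double-loop PR-envelope computation (500 cases)."""
        rng = np.random.default_rng(23)
        for _ in range(500):
            n_truth = int(rng.integers(1, 15))
            n_pred = int(rng.integers(0, 25))
            flags = list(rng.random(n_pred) < 0.5)
            tp = 0
            points = []
            for k, f in enumerate(flags, start=1):
                tp += bool(f)
                points.append((tp / n_truth, tp / k))
            expected = 0.0
            prev_r = 0.0
            for r_level, _ in points:
                if r_level > prev_r:
                    env = max(p for r, p in points if r >= r_level)
                    expected += (r_level - prev_r) * env
                    prev_r = r_level
            assert average_precision(flags, n_truth) == pytest.approx(expected, abs=1e-12)


class TestDetector:
    def test_no_transfected_cells_yields_empty(self):
        spec = SyntheticSpec(seed=5, transfected_fraction=0.0)
        field, truth = generate_field(spec)
        assert truth.boxes == []
        assert detect_cells(field) == []

    def test_easy_field_detects_every_cell(self):
        """Noise-free field: every truth box matched at IoU >= 0.5."""
        spec = SyntheticSpec(seed=6, cells_per_field=(10, 10),
                             transfected_fraction=1.0, noise_multiplier=0.0)
        field, truth = generate_field(spec)
        dets = detect_cells(field)
        assert len(dets) == len(truth.boxes) == 10
        flags, unmatched = match_detections(dets, [a.bbox for a in truth.boxes], 0.5)
        assert all(flags) and unmatched == 0

    def test_determinism(self, clean_field):
        a = detect_cells(clean_field[0])
        b = detect_cells(clean_field[0])
        assert a == b

    def test_scores_ranked_descending(self, clean_field):
        dets = detect_cells(clean_field[0])
        scores = [d.score for d in dets]
        assert scores == sorted(scores, reverse=True)

    def test_missing_channel_error(self):
        from maps_hcm.types import FieldImage

        mono = FieldImage(np.zeros((1, 64, 64), np.float32), ("nucleus",))
        with pytest.raises(KeyError, match="reporter"):
            detect_cells(mono)


class TestNoiseSweep:
    @pytest.fixture(scope="class")
    def sweep_table(self, clean_field_set):
        fields = [f for f, _ in clean_field_set[:8]]
        truths = {f.field_id: [a.bbox for a, _ in zip(t.boxes, t.phenotype_labels)]
                  for (f, t) in clean_field_set[:8]}
        return noise_sweep(fields, truths, multipliers=[0, 1, 3], seed=3), fields, truths

    def test_zero_multiplier_equals_clean_evaluation(self, sweep_table):
        table, fields, truths = sweep_table
        preds = {f.field_id: detect_cells(f) for f in fields}
        clean = evaluate_detections(preds, truths)
        row = table.iloc[0]
        assert row["recall"] == pytest.approx(clean.recall)
        assert row["precision"] == pytest.approx(clean.precision)

    def test_recall_non_increasing_in_noise(self, sweep_table):
        table, _, _ = sweep_table
        recalls = list(table["recall"])
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))

    def test_mean_snr_strictly_decreasing(self, sweep_table):
        table, _, _ = sweep_table
        snrs = list(table["mean_snr"])
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_requires_multipliers(self, clean_field_set):
        with pytest.raises(ValueError):
            noise_sweep([clean_field_set[0][0]], {}, multipliers=[])


class TestAugmentImage:
    @pytest.fixture()
    def boxed_image(self):
        rng = np.random.default_rng(9)
        img = rng.random((3, 64, 64)).astype(np.float32)
        anns = [Annotation("x.tif", "cell", BBox(0.1, 0.2, 0.3, 0.4))]
        return img, anns

    def test_rot180_is_involution(self, boxed_image):
        img, anns = boxed_image
        once_img, once_anns = augment_image(img, anns, "rot180")
        twice_img, twice_anns = augment_image(once_img, once_anns, "rot180")
        assert np.array_equal(twice_img, img)
        b = twice_anns[0].bbox
        assert (b.left, b.top, b.width, b.height) == pytest.approx(
            (0.1, 0.2, 0.3, 0.4)
        )

    def test_flip_h_box_mapping(self, boxed_image):
        img, anns = boxed_image
        _, out = augment_image(img, anns, "flip_h")
        b = out[0].bbox
        assert (b.left, b.top, b.width, b.height) == pytest.approx((0.6, 0.2, 0.3, 0.4))

    def test_four_quarter_rotations_compose_to_identity(self, boxed_image):
        img, anns = boxed_image
        cur_img, cur_anns = img, anns
        for _ in range(4):
            cur_img, cur_anns = augment_image(cur_img, cur_anns, "rot90")
        assert np.array_equal(cur_img, img)
        b = cur_anns[0].bbox
        assert (b.left, b.top, b.width, b.height) == pytest.approx(
            (0.1, 0.2, 0.3, 0.4)
        )

    @pytest.mark.parametrize("tid", ["brightness_up", "contrast_down", "invert",
                                     "noise_low", "noise_high"])
    def test_photometric_transforms_leave_boxes_untouched(self, boxed_image, tid):
        img, anns = boxed_image
        out_img, out_anns = augment_image(img, anns, tid, seed=3)
        assert out_anns[0].bbox == anns[0].bbox
        assert out_img.shape == img.shape

    @pytest.mark.parametrize("tid", ["rot90", "rot270", "flip_v", "rot90_flip_h"])
    def test_geometric_transforms_preserve_box_area(self, boxed_image, tid):
        img, anns = boxed_image
        _, out = augment_image(img, anns, tid)
        assert out[0].bbox.area == pytest.approx(anns[0].bbox.area)

    def test_pixel_content_follows_box_under_rotation(self):
        """The cropped content of a transformed box equals the transformed
        crop, pinning the image/box correspondence."""
        rng = np.random.default_rng(11)
        img = rng.random((1, 40, 40)).astype(np.float32)
        ann = Annotation("x", "cell", BBox(0.25, 0.5, 0.25, 0.25))
        out_img, (out_ann,) = augment_image(img, [ann], "rot90")
        r0, r1, c0, c1 = ann.bbox.to_pixels(40, 40)
        o0, o1, p0, p1 = out_ann.bbox.to_pixels(40, 40)
        crop = img[0, r0:r1, c0:c1]
        out_crop = out_img[0, o0:o1, p0:p1]
        assert np.array_equal(out_crop, np.rot90(crop))

    def test_unknown_transform_lists_valid_ids(self, boxed_image):
        img, anns = boxed_image
        with pytest.raises(ValueError, match="identity"):
            augment_image(img, anns, "shear")

    def test_registry_has_fourteen_transforms(self):
        assert len(TRANSFORM_IDS) == 14 and "identity" in TRANSFORM_IDS


class TestAugmentDataset:
    def test_three_images_become_fortytwo(self, tmp_path):
        spec = SyntheticSpec(seed=2, image_size=128, cells_per_field=(1, 2))
        generate_dataset(spec, 3, tmp_path / "src")
        info = augment_dataset(tmp_path / "src", tmp_path / "aug")
        assert info["n_output"] == 42
        assert len(list((tmp_path / "aug").glob("*.tif"))) == 42

    def test_empty_dataset_passes_through(self, tmp_path):
        (tmp_path / "src").mkdir()
        (tmp_path / "src" / "annotations.csv").write_text(
            "image,tag,left,top,width,height\n"
        )
        info = augment_dataset(tmp_path / "src", tmp_path / "aug")
        assert info["n_output"] == 0

    def test_missing_annotation_csv_rejected(self, tmp_path):
        (tmp_path / "src").mkdir()
        with pytest.raises(FileNotFoundError):
            augment_dataset(tmp_path / "src", tmp_path / "aug")

    def test_augmented_boxes_survive_round_trip(self, tmp_path):
        import pandas as pd

        spec = SyntheticSpec(seed=3, image_size=128, cells_per_field=(2, 2),
                             transfected_fraction=1.0)
        generate_dataset(spec, 1, tmp_path / "src")
        augment_dataset(tmp_path / "src", tmp_path / "aug")
        df = pd.read_csv(tmp_path / "aug" / "annotations.csv")
        # every transform keeps one row per source box, all boxes valid
        assert len(df) == 2 * 14
        for r in df.itertuples():
            BBox(r.left, r.top, r.width, r.height)  # validates invariants
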