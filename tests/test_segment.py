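"""Segmentation stage: metrics oracles, level assignment, assessability, desk segmenter."""

import numpy as np
import pytest

from osteoscreen.imgprep import LT_2_VERTEBRAE
from osteoscreen.phantom import generate_phantom
from osteoscreen.pipeline import segment_sample
from osteoscreen.segment import (
    Instance,
    InstanceSet,
    assessability_filter,
    assign_vertebra_levels,
    average_precision,
    dice_iou,
    segment_vertebrae,
    segmentation_metrics,
    truth_instance_set,
)


def _box_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, bool)
    m[r0:r1, c0:c1] = True
    return m


class TestDiceIou:
    def test_identity_and_disjoint(self):
        a = _box_mask((20, 20), 2, 10, 2, 10)
        assert dice_iou(a, a) == (1.0, 1.0)
        b = _box_mask((20, 20), 12, 18, 12, 18)
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_half_overlapping_squares(self):
        """Two equal squares overlapping half their area: IoU 1/3, Dice 1/2."""
        a = _box_mask((20, 40), 0, 10, 0, 10)
        b = _box_mask((20, 40), 0, 10, 5, 15)
        d, i = dice_iou(a, b)
        assert i == pytest.approx(1 / 3)
        assert d == pytest.approx(1 / 2)

    def test_dice_iou_functional_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a = rng.uniform(size=(15, 15)) > 0.5
            b = rng.uniform(size=(15, 15)) > 0.5
            if not (a.any() or b.any()):
                continue
            d, i = dice_iou(a, b)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)


class TestLevelAssignment:
    def _instances(self, rows, scores=None):
        shape = (100, 30)
        scores = scores or [1.0] * len(rows)
        return InstanceSet(
            [
                Instance("vertebra", _box_mask(shape, r, r + 10, 5, 25), s)
                for r, s in zip(rows, scores)
            ]
        )

    def test_top_down_labelling(self):
        out = assign_vertebra_levels(self._instances([5, 30, 55, 80]))
        assert [i.level for i in out.instances] == ["L1", "L2", "L3", "L4"]
        assert not out.level_uncertain

    def test_lowest_score_extra_dropped(self):
        out = assign_vertebra_levels(self._instances([5, 25, 45, 65, 85], [0.9, 0.8, 0.95, 0.3, 0.7]))
        verts = [i for i in out.instances if i.cls == "vertebra"]
        assert len(verts) == 4
        assert all(i.level != "unassigned" for i in verts)
        # the 0.3-score instance (rows 65-75) is gone
        assert not any(i.mask[66, 10] for i in verts)

    def test_two_instances_flagged_uncertain(self):
        out = assign_vertebra_levels(self._instances([10, 40]))
        assert [i.level for i in out.instances] == ["L1", "L2"]
        assert out.level_uncertain

    def test_permutation_invariance(self):
        base = self._instances([5, 30, 55, 80], [0.9, 0.8, 0.7, 0.6])
        shuffled = InstanceSet(list(reversed(base.instances)))
        a = assign_vertebra_levels(base)
        b = assign_vertebra_levels(shuffled)
        for la, lb in zip(a.instances, b.instances):
            assert la.level == lb.level
            np.testing.assert_array_equal(la.mask, lb.mask)

    def test_duplicate_overlap_resolved_by_score(self):
        shape = (100, 30)
        m = _box_mask(shape, 10, 30, 5, 25)
        dup = np.roll(m, 2, axis=0)
        out = assign_vertebra_levels(
            InstanceSet([Instance("vertebra", m, 0.9), Instance("vertebra", dup, 0.6)])
        )
        verts = [i for i in out.instances if i.cls == "vertebra"]
        assert len(verts) == 1 and verts[0].score == 0.9


class TestAssessability:
    def _with_implant(self, covered_levels, n=4):
        shape = (200, 40)
        instances = [
            Instance("vertebra", _box_mask(shape, 10 + 45 * k, 40 + 45 * k, 5, 35), 1.0, f"L{k+1}")
            for k in range(n)
        ]
        for lvl in covered_levels:
            k = int(lvl[1]) - 1
            instances.append(Instance("implant", _box_mask(shape, 10 + 45 * k, 30 + 45 * k, 0, 40), 1.0))
        return InstanceSet(instances)

    def test_half_covered_vertebra_non_assessable_but_eligible(self):
        out, reasons = assessability_filter(self._with_implant(["L3"]))
        flags = {i.level: i.assessable for i in out.instances if i.cls == "vertebra"}
        assert flags == {"L1": True, "L2": True, "L3": False, "L4": True}
        assert reasons == []

    def test_three_covered_vertebrae_ineligible(self):
        _, reasons = assessability_filter(self._with_implant(["L1", "L2", "L3"]))
        assert reasons == [LT_2_VERTEBRAE]

    def test_no_implant_identity(self):
        out, reasons = assessability_filter(self._with_implant([]))
        assert all(i.assessable for i in out.instances)
        assert reasons == []


class TestAveragePrecision:
    def test_perfect_predictions(self):
        t = [_box_mask((30, 30), 0, 10, 0, 10), _box_mask((30, 30), 15, 25, 15, 25)]
        dets = [(0.9, t[0].copy()), (0.8, t[1].copy())]
        assert average_precision(dets, t) == pytest.approx(1.0)

    def test_no_truth_is_undefined(self):
        assert average_precision([(0.9, _box_mask((10, 10), 0, 5, 0, 5))], []) is None

    def test_agrees_with_greedy_oracle_on_small_sets(self):
        """AP equals a directly coded greedy matcher + PR integration on <=5 instances."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n_t = int(rng.integers(1, 5))
            n_d = int(rng.integers(0, 6))
            truths = []
            for _k in range(n_t):
                r, c = rng.integers(0, 20, 2)
                truths.append(_box_mask((40, 40), r, r + 12, c, c + 12))
            dets = []
            for _k in range(n_d):
                r, c = rng.integers(0, 22, 2)
                dets.append((float(rng.uniform()), _box_mask((40, 40), r, r + 12, c, c + 12)))
            ap = average_precision(dets, truths, iou_threshold=0.5)

            # oracle: same protocol coded independently
            order = sorted(range(n_d), key=lambda k: -dets[k][0])
            used = set()
            flags = []
            for k in order:
                best, bj = 0.0, None
                for j, t in enumerate(truths):
                    if j in used:
                        continue
                    iou = dice_iou(dets[k][1], t)[1]
                    if iou > best:
                        best, bj = iou, j
                if bj is not None and best >= 0.5:
                    used.add(bj)
                    flags.append(True)
                else:
                    flags.append(False)
            tp = np.cumsum(flags) if flags else np.array([])
            expected = 0.0
            if len(tp):
                rec = tp / n_t
                prec = tp / np.arange(1, len(tp) + 1)
                env = np.maximum.accumulate(prec[::-1])[::-1]
                prev = 0.0
                for r_, p_ in zip(rec, env):
                    expected += (r_ - prev) * p_
                    prev = r_
            assert ap == pytest.approx(expected, abs=1e-12)


class TestSegmentationMetrics:
    def test_identity_is_perfect(self, one_phantom):
        truth = truth_instance_set(one_phantom)
        m = segmentation_metrics(truth, truth)
        assert m.map_75 == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in m.dice_per_level.values())
        assert m.region_dice == pytest.approx(1.0)

    def test_empty_truth_flagged_undefined(self):
        pred = InstanceSet([Instance("vertebra", _box_mask((10, 10), 0, 5, 0, 5), 1.0, "L1")])
        m = segmentation_metrics(pred, InstanceSet([]))
        assert m.undefined and m.map_75 is None


class TestDeskSegmenter:
    def test_blank_image_yields_empty_set(self, trained_segmenter):
        out = segment_vertebrae(np.zeros((1024, 1024), np.uint8), trained_segmenter)
        assert out.instances == []

    def test_augmentations_recorded(self, trained_segmenter):
        aug = trained_segmenter.augmentations
        assert aug["horizontal_flip"] and aug["brightness_delta"] > 0
        assert aug["rotation_deg"] > 0 and aug["contrast_range"][0] < 1 < aug["contrast_range"][1]

    def test_masks_in_native_resolution(self, implant_config, trained_segmenter):
        sample = generate_phantom(implant_config, 777)
        pred = segment_sample(sample, trained_segmenter)
        for inst in pred.instances:
            assert inst.mask.shape == sample.image.shape

    def test_held_out_region_dice_and_implant_detection(self, implant_config, trained_segmenter):
        dices = []
        implant_hit = 0
        implant_total = 0
        for seed in range(6):
            sample = generate_phantom(implant_config, 600 + seed)
            pred = segment_sample(sample, trained_segmenter)
            truth = truth_instance_set(sample)
            m = segmentation_metrics(pred, truth)
            dices.append(m.region_dice)
            if "implant" in sample.masks:
                implant_total += 1
                best = max(
                    (dice_iou(p.mask, sample.masks["implant"])[1] for p in pred.implants()),
                    default=0.0,
                )
                implant_hit += best >= 0.5
        assert float(np.mean(dices)) >= 0.85
        if implant_total:
            assert implant_hit >= implant_total * 0.5

    def test_training_deterministic(self, implant_config):
        from osteoscreen.segment import train_segmenter

        train = [generate_phantom(implant_config, 500 + i) for i in range(4)]
        a = train_segmenter(train, seed=3, px_per_image=600)
        b = train_segmenter(train, seed=3, px_per_image=600)
        for ca, cb in zip(a.model.coefs_, b.model.coefs_):
            np.testing.assert_allclose(ca, cb)
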