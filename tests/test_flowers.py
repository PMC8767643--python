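import itertools
import random

import numpy as np
import pytest

from phenotyper import flowers as fl
from phenotyper import segmentation as seg
from phenotyper import synth


def _yellow_disc_image(shape=(80, 80), center=(40, 40), radius=10):
    """Green background square with a yellow disc inside it."""
    img = np.zeros(shape + (3,), np.uint8)
    img[...] = (46, 115, 46)  # leaf green
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[disc] = (235, 215, 40)
    return img, disc


class TestFlowerMask:
    def test_all_green_plant_has_no_flowers(self):
        img = np.full((40, 40, 3), (46, 115, 46), np.uint8)
        mask = fl.flower_mask(img, np.ones((40, 40), bool), fl.default_policy(), 45, "control")
        assert not mask.any()

    def test_yellow_disc_recovered(self):
        img, disc = _yellow_disc_image()
        mask = fl.flower_mask(img, np.ones(img.shape[:2], bool), fl.default_policy(), 45, "control")
        np.testing.assert_array_equal(mask, disc)

    def test_yellow_outside_plant_mask_excluded(self):
        img, disc = _yellow_disc_image(center=(20, 20))
        plant = np.zeros(img.shape[:2], bool)
        plant[40:, 40:] = True  # plant elsewhere
        mask = fl.flower_mask(img, plant, fl.default_policy(), 45, "control")
        assert not mask.any()

    def test_flower_pixels_subset_of_plant_pixels(self):
        plant = synth.render_plant(synth.GenotypeParams(), das=49, seed=9)
        pmask = seg.segment(plant.rgb_top)
        fmask = fl.flower_mask(plant.rgb_top, pmask, fl.default_policy(), 49, "control")
        assert not (fmask & ~pmask).any()

    def test_unmatched_policy_rule_rejected(self):
        policy = fl.FlowerThresholdPolicy(rules=[fl.ThresholdRule(50, 60, "drought", 60.0)])
        img, _ = _yellow_disc_image()
        with pytest.raises(seg.ConfigError, match="no flower-threshold rule"):
            fl.flower_mask(img, np.ones(img.shape[:2], bool), policy, 45, "control")

    def test_first_matching_rule_wins(self):
        policy = fl.FlowerThresholdPolicy(
            rules=[fl.ThresholdRule(40, 60, "any", 200.0), fl.ThresholdRule(1, 365, "any", 10.0)]
        )
        assert policy.threshold(45, "control") == 200.0
        assert policy.threshold(39, "control") == 10.0


def _blob_mask(sizes, shape=(60, 200)):
    """Disjoint rectangles of the given pixel counts (width 10)."""
    m = np.zeros(shape, bool)
    x = 2
    for s in sizes:
        h = s // 10
        m[2 : 2 + h, x : x + 10] = True
        x += 14
    return m


class TestExtractComponents:
    def test_minimum_size_filter(self):
        m = _blob_mask([50, 120, 400])
        comps = fl.extract_components(m)
        assert sorted(c.pixel_count for c in comps) == [120, 400]

    def test_component_of_exactly_minimum_size_kept(self):
        m = _blob_mask([100])
        assert len(fl.extract_components(m)) == 1

    def test_empty_mask_gives_empty_set(self):
        assert fl.extract_components(np.zeros((10, 10), bool)) == []

    def test_descriptive_properties(self):
        m = np.zeros((20, 20), bool)
        m[2:12, 3:13] = True  # 10x10 square
        (comp,) = fl.extract_components(m)
        assert comp.pixel_count == 100
        assert comp.bbox == (3, 2, 13, 12)
        assert comp.bbox_area == 100
        assert comp.centroid == (7.5, 6.5)
        assert comp.hull_area == pytest.approx(81.0)  # 9x9 hull of pixel centers


class TestDetectAnthesis:
    def _comps(self, n):
        m = _blob_mask([120] * n) if n else np.zeros((4, 4), bool)
        return fl.extract_components(m)

    def test_first_day_with_component(self):
        series = {35: self._comps(0), 37: self._comps(0), 39: self._comps(1)}
        assert fl.detect_anthesis(series) == 39

    def test_never_flowering_gives_none(self):
        series = {35: self._comps(0), 37: self._comps(0)}
        assert fl.detect_anthesis(series) is None

    def test_flowering_on_first_imaged_day(self):
        assert fl.detect_anthesis({35: self._comps(2)}) == 35


class TestEstimateFlowerCount:
    def test_single_flower_below_split_threshold(self):
        comps = fl.extract_components(_blob_mask([120]))
        assert fl.estimate_flower_count(comps, flower_ref_px=150) == 1

    def test_large_component_split_by_reference_area(self):
        comps = fl.extract_components(_blob_mask([450]))
        assert fl.estimate_flower_count(comps, flower_ref_px=150) == 3

    def test_empty_set_counts_zero(self):
        assert fl.estimate_flower_count([], flower_ref_px=150) == 0

    def test_round_half_up(self):
        comps = fl.extract_components(_blob_mask([370]))  # 370/150 = 2.47 -> 2
        assert fl.estimate_flower_count(comps, flower_ref_px=150) == 2
        comps = fl.extract_components(_blob_mask([380]))  # 2.53 -> 3
        assert fl.estimate_flower_count(comps, flower_ref_px=150) == 3

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(seg.ConfigError):
            fl.estimate_flower_count([], flower_ref_px=0)


class TestCanopyMetrics:
    def test_width_spans_all_bounding_boxes(self):
        m = np.zeros((40, 130), bool)
        m[5:17, 10:22] = True
        m[20:32, 98:110] = True
        comps = fl.extract_components(m)
        width, _ = fl.canopy_metrics(comps, plant_height_px=50)
        assert width == 100.0

    def test_right_angle_apex(self):
        m = np.zeros((40, 130), bool)
        m[5:17, 10:22] = True
        m[20:32, 98:110] = True
        comps = fl.extract_components(m)
        _, angle = fl.canopy_metrics(comps, plant_height_px=50)
        assert angle == pytest.approx(90.0)

    def test_single_component_width_is_its_bbox_width(self):
        m = np.zeros((40, 40), bool)
        m[5:17, 10:22] = True
        comps = fl.extract_components(m)
        width, _ = fl.canopy_metrics(comps, plant_height_px=30)
        assert width == 12.0

    def test_empty_set_gives_missing(self):
        assert fl.canopy_metrics([], plant_height_px=30) == (None, None)


def _component_at(x, y, size=12):
    return fl.FlowerComponent(
        pixel_count=size * size,
        centroid=(x + size / 2, y + size / 2),
        bbox=(x, y, x + size, y + size),
        bbox_area=size * size,
        hull_area=float((size - 1) ** 2),
    )


class TestClusterRacemes:
    def test_two_separated_groups_recovered(self):
        """Exhaustive oracle on 6 points: the only 2-partition whose maximum
        within-cluster diameter is small is the spatial grouping itself."""
        group_a = [_component_at(0, 0), _component_at(20, 5), _component_at(5, 18)]
        group_b = [_component_at(500, 500), _component_at(520, 490), _component_at(510, 515)]
        comps = group_a + group_b

        def diameter(idxs):
            pts = [comps[i].feature_vector for i in idxs]
            return max(
                (np.linalg.norm(p - q) for p, q in itertools.combinations(pts, 2)),
                default=0.0,
            )

        best = min(
            (frozenset(sub) for r in range(1, 6) for sub in itertools.combinations(range(6), r)),
            key=lambda sub: max(diameter(sub), diameter(set(range(6)) - sub)),
        )
        assert best in (frozenset({0, 1, 2}), frozenset({3, 4, 5}))

        labels = fl.cluster_racemes(comps, k=2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k1_single_label(self):
        comps = [_component_at(i * 30, 0) for i in range(4)]
        assert set(fl.cluster_racemes(comps, k=1)) == {1}

    def test_k_equals_n_each_its_own_branch(self):
        comps = [_component_at(i * 30, 0) for i in range(4)]
        assert sorted(fl.cluster_racemes(comps, k=4)) == [1, 2, 3, 4]

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            fl.cluster_racemes([_component_at(0, 0)], k=2)

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        comps = [
            _component_at(float(rng.uniform(0, 40) + 300 * (i % 3)), float(rng.uniform(0, 40)))
            for i in range(9)
        ]
        base = fl.cluster_racemes(comps, k=3)

        def partition(order, labels):
            groups = {}
            for pos, lab in zip(order, labels):
                groups.setdefault(lab, set()).add(pos)
            return frozenset(frozenset(g) for g in groups.values())

        ref = partition(range(9), base)
        py_rng = random.Random(0)
        for _ in range(5):
            order = list(range(9))
            py_rng.shuffle(order)
            labels = fl.cluster_racemes([comps[i] for i in order], k=3)
            assert partition(order, labels) == ref
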