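"""Salt-split-skin pipeline: attention lines, sampling, patch net,
aggregation, and the composed per-side inference."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from iifseg.segmentation import SegmentationResult, segment
from iifseg.sss import (PATCH_LABELS, Patch, PatchNetConfig, PatchResult,
                        aggregate, classify_patches, classify_side,
                        compute_attention_lines, sample_patches,
                        train_patch_net)
from iifseg.synthetic import SPLIT_SKIN_CLASSES, SceneSpec, generate_image
from iifseg.training import build_sss_patch_dataset
from iifseg.features import patch_features

R, F, I, BG = (SPLIT_SKIN_CLASSES[k] for k in
               ("roof", "floor", "interspace", "background"))


def _seg_from_map(class_map: np.ndarray) -> SegmentationResult:
    probs = np.eye(4)[class_map]
    return SegmentationResult(class_probs=probs, class_map=class_map,
                              working_size=class_map.shape,
                              substrate="split_skin")


from test_imaging import brute_force_dilate  # noqa: E402


def attention_oracle(class_map: np.ndarray):
    """Literal evaluation of the two set equations with the brute-force
    shift-enumeration dilation from the imaging tests."""
    r = brute_force_dilate(class_map == R, 3)
    f = brute_force_dilate(class_map == F, 3)
    i = brute_force_dilate(class_map == I, 3)
    return r & (f | i), f & (r | i)


class TestAttentionLines:
    def test_horizontal_band_example(self):
        cm = np.full((10, 10), F)
        cm[0:4] = R
        cm[4:6] = I
        lines = compute_attention_lines(_seg_from_map(cm))
        expected_roof = np.zeros((10, 10), dtype=bool)
        expected_roof[3:5] = True  # DIL(R)=rows 0-4 with DIL(I)=rows 3-6
        expected_floor = np.zeros((10, 10), dtype=bool)
        expected_floor[5:7] = True
        assert np.array_equal(lines.roof_line, expected_roof)
        assert np.array_equal(lines.floor_line, expected_floor)

    def test_all_background_gives_empty_lines(self):
        lines = compute_attention_lines(_seg_from_map(np.full((12, 12), BG)))
        assert not lines.roof_line.any() and not lines.floor_line.any()

    def test_roof_without_floor_or_interspace_gives_empty_roof_line(self):
        cm = np.full((12, 12), BG)
        cm[2:6] = R
        lines = compute_attention_lines(_seg_from_map(cm))
        assert not lines.roof_line.any()

    @given(st.integers(0, 10_000))
    def test_matches_set_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 4, size=(rng.integers(8, 64), rng.integers(8, 64)))
        lines = compute_attention_lines(_seg_from_map(cm))
        roof, floor = attention_oracle(cm)
        assert np.array_equal(lines.roof_line, roof)
        assert np.array_equal(lines.floor_line, floor)


class TestSamplePatches:
    def test_empty_line_gives_all_padding(self):
        img = np.zeros((512, 512))
        patches = sample_patches(img, np.zeros((128, 128), dtype=bool))
        assert len(patches) == 40
        assert all(p.is_padding for p in patches)

    def test_dense_straight_line_radius_24(self):
        img = np.zeros((256, 2100))
        line = np.zeros((256, 2100), dtype=bool)
        line[128, 50:2050] = True  # length 2000
        patches = sample_patches(img, line, radius=24.0, seed=4, scale_factor=1)
        real = [p for p in patches if not p.is_padding]
        assert len(real) == 40
        centers = np.array([p.center for p in real], dtype=float)
        d = np.hypot(*(centers[:, None] - centers[None]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 24.0

    def test_same_seed_same_centers(self):
        rng = np.random.default_rng(1)
        line = rng.random((128, 128)) < 0.02
        img = rng.random((512, 512))
        a = sample_patches(img, line, seed=7)
        b = sample_patches(img, line, seed=7)
        assert [p.center for p in a] == [p.center for p in b]

    def test_patches_fully_inside_bounds(self):
        line = np.zeros((128, 128), dtype=bool)
        line[0, :] = True  # line at the top edge maps near the border
        img = np.random.default_rng(0).random((512, 512))
        for p in sample_patches(img, line, seed=2):
            if not p.is_padding:
                assert p.pixels.shape == (64, 64)
                r, c = p.center
                assert 32 <= r <= 512 - 32 and 32 <= c <= 512 - 32


def _result(label, prob, brightness=1.0):
    idx = PATCH_LABELS.index(label)
    probs = np.full(4, (1 - prob) / 3)
    probs[idx] = prob
    return PatchResult(label_probs=probs, brightness=brightness)


class TestAggregate:
    def test_no_informative_patches_gives_half(self):
        res = aggregate([_result("unclear", 0.9)] * 5)
        assert res.y == 0.5
        assert res.n_informative == 0
        assert res.b is None

    def test_printed_formula_hand_example(self):
        res = aggregate([_result("positive", 0.9), _result("positive", 0.7),
                         _result("negative", 0.6)])
        assert res.y_pos == pytest.approx(0.8)
        assert res.y_neg == pytest.approx(0.6)
        assert res.y == pytest.approx(0.6)

    def test_brightness_mean_of_top3_positive_probability(self):
        results = [_result("positive", p, b) for p, b in
                   zip([0.9, 0.8, 0.7, 0.6, 0.5], [1, 2, 3, 4, 5])]
        assert aggregate(results).b == pytest.approx(2.0)

    def test_fewer_than_three_positives_average_available(self):
        results = [_result("positive", 0.9, 4.0), _result("positive", 0.8, 2.0)]
        assert aggregate(results).b == pytest.approx(3.0)

    def test_background_and_unclear_do_not_influence_result(self):
        core = [_result("positive", 0.9, 3.5), _result("negative", 0.7)]
        base = aggregate(core)
        padded = aggregate(core + [_result("background", 0.99, 9.9)] * 7
                           + [_result("unclear", 0.8, -1.0)] * 5)
        assert padded.y == base.y
        assert padded.b == base.b
        assert padded.n_informative == base.n_informative

    @given(st.integers(0, 5000))
    def test_y_bounded_for_arbitrary_results(self, seed):
        rng = np.random.default_rng(seed)
        results = [_result(rng.choice(PATCH_LABELS), rng.uniform(0.3, 1.0),
                           rng.uniform(1, 5)) for _ in range(rng.integers(1, 12))]
        assert 0.0 <= aggregate(results).y <= 1.0

    @given(st.integers(0, 5000))
    def test_monotone_under_neg_to_pos_swap_at_equal_confidence(self, seed):
        # with every informative patch at the same confidence, converting a
        # negative vote into a positive one never decreases y (the means
        # are confidence-invariant, only the side memberships change)
        rng = np.random.default_rng(seed)
        conf = float(rng.uniform(0.4, 1.0))
        labels = [rng.choice(PATCH_LABELS) for _ in range(rng.integers(1, 12))]
        results = [_result(l, conf, 3.0) for l in labels]
        base = aggregate(results)
        neg_idx = [i for i, r in enumerate(results)
                   if r.argmax_label == "negative"]
        if neg_idx:
            swapped = list(results)
            swapped[neg_idx[0]] = _result("positive", conf, 3.0)
            assert aggregate(swapped).y >= base.y - 1e-12


class TestPatchNet:
    def test_padding_patch_classified_background(self, roof_model):
        res = classify_patches(roof_model, [Patch(np.zeros((64, 64)), (-1, -1),
                                                  "roof", is_padding=True)])[0]
        assert res.argmax_label == "background"
        assert res.label_probs[PATCH_LABELS.index("background")] > 0.5

    def test_probabilities_sum_to_one_and_pure(self, roof_model, rng):
        patch = Patch(rng.random((64, 64)), (100, 100), "roof")
        r1, r2 = classify_patches(roof_model, [patch, patch])
        assert abs(r1.label_probs.sum() - 1.0) < 1e-5
        assert np.array_equal(r1.label_probs, r2.label_probs)

    def test_heldout_patch_label_accuracy(self, roof_model, sss_test_scenes):
        data = build_sss_patch_dataset(sss_test_scenes, "roof", seed=17)
        X = np.array([patch_features(p) for p, _, _ in data])
        truth = [l for _, l, _ in data]
        pred = [PATCH_LABELS[i]
                for i in roof_model.net.predict(X)["label"].argmax(axis=1)]
        acc = np.mean([a == b for a, b in zip(pred, truth)])
        assert acc >= 0.85

    def test_training_deterministic(self, sss_test_scenes):
        data = build_sss_patch_dataset(sss_test_scenes[:3], "floor", seed=2)
        cfg = PatchNetConfig(epochs=3, seed=8)
        m1 = train_patch_net(data, "floor", cfg)
        m2 = train_patch_net(data, "floor", cfg)
        for a, b in zip(m1.net.Ws, m2.net.Ws):
            assert np.array_equal(a, b)

    def test_invalid_side_and_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_patch_net([], "roof")
        with pytest.raises(ValueError):
            train_patch_net([(np.zeros((64, 64)), "positive", 3.0)], "ceiling")


class TestClassifySide:
    def test_negative_image_negative_on_both_sides(self, sss_seg_model,
                                                   roof_model, floor_model,
                                                   sss_test_scenes):
        img, gt = next((i, g) for i, g in sss_test_scenes if not g.pattern_labels)
        seg = segment(sss_seg_model, img)
        for side, model in (("roof", roof_model), ("floor", floor_model)):
            call, _ = classify_side(img, seg, model, side, seed=1)
            assert call == "negative"

    def test_epidermal_image_roof_positive_floor_negative(self, sss_seg_model,
                                                          roof_model,
                                                          floor_model):
        spec = SceneSpec(substrate="split_skin", pattern="epidermal",
                         pattern_brightness=0.9, geometry_seed=123,
                         output_size=(512, 512))
        img, _ = generate_image(spec, 55)
        seg = segment(sss_seg_model, img)
        assert classify_side(img, seg, roof_model, "roof", seed=1)[0] == "positive"
        assert classify_side(img, seg, floor_model, "floor", seed=1)[0] == "negative"

    def test_tie_at_threshold_goes_to_positive(self, monkeypatch, sss_seg_model,
                                               roof_model, sss_test_scenes):
        crafted = [_result("positive", 0.8, 3.0), _result("negative", 0.8)]
        monkeypatch.setattr("iifseg.sss.classify_patches",
                            lambda model, patches: crafted)
        img, _ = sss_test_scenes[0]
        seg = segment(sss_seg_model, img)
        call, res = classify_side(img, seg, roof_model, "roof", seed=1)
        assert res.y == pytest.approx(0.5)
        assert call == "positive"


class TestThresholdCalibration:
    def test_calibrated_thresholds_stored_and_bounded(self, sss_train_scenes,
                                                      sss_seg_model,
                                                      roof_model, floor_model):
        from copy import deepcopy
        from iifseg.experiments import calibrate_side_thresholds
        roof = deepcopy(roof_model)
        floor = deepcopy(floor_model)
        calibrate_side_thresholds(sss_train_scenes[:16], sss_seg_model,
                                  roof, floor, seed=1)
        for model in (roof, floor):
            assert 0.05 <= model.threshold <= 0.95

    def test_threshold_roundtrips_with_model(self, roof_model, tmp_path):
        from copy import deepcopy
        from iifseg.sss import PatchModel
        model = deepcopy(roof_model)
        model.threshold = 0.42
        path = tmp_path / "roof.npz"
        model.save(path)
        assert PatchModel.load(path).threshold == 0.42
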