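"""Synthetic scene generator: determinism, signal, masks, dilution series."""

import numpy as np
import pandas as pd
import pytest

from iifseg.synthetic import (ESOPHAGUS_CLASSES, SPLIT_SKIN_CLASSES, GenConfig,
                              SceneSpec, dilution_brightness, generate_dataset,
                              generate_dilution_series, generate_image,
                              render_scenes)
from iifseg.training import truth_attention_line

SIZE = (256, 256)


def _spec(**kw):
    base = dict(substrate="split_skin", pattern="none", pattern_brightness=0.0,
                geometry_seed=4, noise_sd=0.02, output_size=SIZE)
    base.update(kw)
    return SceneSpec(**base)


class TestSceneSpecValidation:
    def test_pattern_must_match_substrate(self):
        with pytest.raises(ValueError, match="invalid"):
            _spec(substrate="esophagus", pattern="epidermal",
                  pattern_brightness=0.5)

    def test_minimum_canvas_size(self):
        with pytest.raises(ValueError):
            _spec(output_size=(128, 128))

    def test_active_pattern_needs_positive_brightness(self):
        spec = _spec(pattern="epidermal", pattern_brightness=0.0)
        with pytest.raises(ValueError):
            generate_image(spec, 1)

    def test_unknown_confounder_rejected(self):
        with pytest.raises(ValueError):
            _spec(confounder="dust")


class TestGenerateImage:
    def test_identical_spec_and_seed_byte_identical(self):
        spec = _spec(pattern="epidermal", pattern_brightness=0.7)
        a, _ = generate_image(spec, 9)
        b, _ = generate_image(spec, 9)
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_noise_free_negative_scene_is_flat(self):
        # with no pattern and noise_sd=0 the rendering is piecewise
        # constant: the split boundary carries exactly the tissue base
        # intensity, no band
        img, gt = generate_image(_spec(noise_sd=0.0), 3)
        roof = gt.seg_mask == SPLIT_SKIN_CLASSES["roof"]
        line = truth_attention_line(gt.seg_mask, "roof")
        assert img.pixels[line & roof].max() == img.pixels[roof].max()
        assert len(np.unique(img.pixels)) <= 4  # one value per class

    def test_epidermal_band_brighter_than_floor_boundary(self):
        img, gt = generate_image(
            _spec(pattern="epidermal", pattern_brightness=1.0), 5)
        roof_band = truth_attention_line(gt.seg_mask, "roof")
        floor_band = truth_attention_line(gt.seg_mask, "floor")
        assert img.pixels[roof_band].mean() - img.pixels[floor_band].mean() > 0

    def test_band_contrast_monotone_in_brightness(self):
        means = []
        for beta in (0.2, 0.5, 0.8):
            img, gt = generate_image(
                _spec(pattern="epidermal", pattern_brightness=beta,
                      noise_sd=0.0), 5)
            band = gt.pattern_masks["epidermal"]
            outside = (gt.seg_mask == SPLIT_SKIN_CLASSES["roof"]) & ~band
            means.append(img.pixels[band].mean() - img.pixels[outside].mean())
        assert means[0] < means[1] < means[2]

    def test_pattern_masks_stay_inside_their_regions(self):
        img, gt = generate_image(
            _spec(pattern="both", pattern_brightness=(0.8, 0.6)), 2)
        mask = gt.seg_mask
        roof_zone = ((mask == SPLIT_SKIN_CLASSES["roof"])
                     | (mask == SPLIT_SKIN_CLASSES["interspace"]))
        floor_zone = ((mask == SPLIT_SKIN_CLASSES["floor"])
                      | (mask == SPLIT_SKIN_CLASSES["interspace"]))
        assert (gt.pattern_masks["epidermal"] <= roof_zone).all()
        assert (gt.pattern_masks["dermal"] <= floor_zone).all()

    def test_eso_patterns_inside_their_classes(self):
        spec = _spec(substrate="esophagus", pattern="both",
                     pattern_brightness=0.8)
        img, gt = generate_image(spec, 6)
        assert (gt.pattern_masks["BMZ"]
                <= (gt.seg_mask == ESOPHAGUS_CLASSES["bmz"])).all()
        assert (gt.pattern_masks["intercellular"]
                <= (gt.seg_mask == ESOPHAGUS_CLASSES["epithelium"])).all()

    def test_brightness_score_present_iff_pattern_active(self):
        _, neg = generate_image(_spec(), 1)
        _, pos = generate_image(_spec(pattern="dermal", pattern_brightness=0.5), 1)
        assert neg.brightness == {} and neg.pattern_labels == set()
        assert pos.brightness == {"dermal": pytest.approx(3.0)}

    def test_mask_matches_image_shape_and_class_set(self):
        img, gt = generate_image(_spec(substrate="esophagus"), 8)
        assert gt.seg_mask.shape == img.pixels.shape
        assert set(np.unique(gt.seg_mask)) <= set(ESOPHAGUS_CLASSES.values())


class TestDilutionSeries:
    def test_endpoint_below_first_dilution_all_negative(self):
        series = generate_dilution_series(
            _spec(pattern="epidermal", pattern_brightness=1.0),
            titer_index=1, n_dilutions=3, seed=0)
        assert all(gt.pattern_labels == set() for _, gt, _ in series)

    def test_brightness_strictly_decreasing_then_zero(self):
        series = generate_dilution_series(
            _spec(pattern="epidermal", pattern_brightness=1.0),
            titer_index=3, n_dilutions=3, seed=0)
        b1 = series[0][1].brightness["epidermal"]
        b2 = series[1][1].brightness["epidermal"]
        assert b1 > b2 > 1.0
        assert series[2][1].pattern_labels == set()

    def test_single_dilution_positive_iff_titer_above_one(self):
        for titer, expect in ((1, set()), (2, {"dermal"})):
            series = generate_dilution_series(
                _spec(pattern="dermal", pattern_brightness=1.0),
                titer_index=titer, n_dilutions=1, seed=3)
            assert len(series) == 1
            assert series[0][1].pattern_labels == expect

    def test_elements_reproducible_from_seed_and_index(self):
        spec = _spec(pattern="epidermal", pattern_brightness=1.0)
        a = generate_dilution_series(spec, 3, 3, seed=5)
        b = generate_dilution_series(spec, 3, 3, seed=5)
        for (ia, _, _), (ib, _, _) in zip(a, b):
            assert ia.pixels.tobytes() == ib.pixels.tobytes()

    def test_score_drops_one_per_step_for_small_titers(self):
        # consistency with the additive titer rule d_{k+s-1}
        assert dilution_brightness(4, 1) - dilution_brightness(4, 2) \
            == pytest.approx(0.25)


class TestGenerateDataset:
    def test_manifest_histogram_matches_requested_counts(self, tmp_path):
        cfg = GenConfig(substrate="split_skin",
                        counts={"epidermal": 3, "dermal": 2, "none": 4},
                        out_dir=str(tmp_path), output_size=SIZE, seed=1)
        manifest = generate_dataset(cfg)
        assert manifest["pattern"].value_counts().to_dict() == {
            "none": 4, "epidermal": 3, "dermal": 2}
        for _, row in manifest.iterrows():
            assert (tmp_path / row["image_path"].split("/")[-1]).exists()

    def test_negatives_only(self, tmp_path):
        cfg = GenConfig(substrate="esophagus", counts={"none": 5},
                        out_dir=str(tmp_path), output_size=SIZE, seed=2)
        manifest = generate_dataset(cfg)
        assert len(manifest) == 5
        assert (manifest["pattern"] == "none").all()

    def test_empty_config_empty_manifest(self, tmp_path):
        cfg = GenConfig(substrate="split_skin", counts={},
                        out_dir=str(tmp_path), output_size=SIZE)
        manifest = generate_dataset(cfg)
        assert manifest.empty
        assert not list(tmp_path.glob("img_*"))

    def test_rerun_identical(self, tmp_path):
        cfg = dict(substrate="split_skin", counts={"none": 2},
                   out_dir=str(tmp_path / "a"), output_size=SIZE, seed=7)
        m1 = generate_dataset(GenConfig.from_dict(cfg))
        cfg["out_dir"] = str(tmp_path / "b")
        m2 = generate_dataset(GenConfig.from_dict(cfg))
        assert list(m1["seed"]) == list(m2["seed"])
        from iifseg.imaging import load_green
        for p1, p2 in zip(m1["image_path"], m2["image_path"]):
            assert load_green(p1).pixels.tobytes() == load_green(p2).pixels.tobytes()
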