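"""Esophagus pipeline: BMZ-mask attention classification, desmosome-region
post-processing, and quantile intensity extraction.

The 7-class segmentation provides the position of the thin epidermal
basement membrane zone (BMZ). The classifier receives two inputs — the
fluorescence image and the binary BMZ mask — and outputs one independent
probability per pattern ('BMZ', 'intercellular'); 'negative' is the absence
of any call, so dual-positive sera remain representable. Pattern intensity
is read out as a fixed quantile of the pixel intensities inside the
pattern's region: the BMZ class itself for linear BMZ staining, and a band
of the epithelium adjacent to the BMZ (the desmosome region, obtained by
iterated dilation of the BMZ mask intersected with the epithelium class)
for intercellular staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .features import eso_features, ESO_FEATURE_NAMES
from .imaging import LabeledImage, resize_mask_to, resize_to
from .segmentation import SegmentationResult, SegModel, segment
from .synthetic import ESOPHAGUS_CLASSES

__all__ = [
    "ESO_PATTERNS", "EsoClassification", "RegionIntensity", "EsoNetConfig",
    "EsoModel", "extract_bmz_mask", "desmosome_region", "region_intensity",
    "classify_eso", "train_eso_classifier", "pattern_region",
]

ESO_PATTERNS = ("BMZ", "intercellular")


@dataclass
class EsoClassification:
    probs: dict[str, float]  # independent per-pattern probabilities
    calls: set[str]

    @property
    def negative(self) -> bool:
        return not self.calls

    def __post_init__(self):
        for p, v in self.probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability for {p} outside [0,1]: {v}")


@dataclass
class RegionIntensity:
    """Quantile intensity of a pattern's region, with the score mapping."""

    region: np.ndarray
    raw_intensity: float
    score: float
    quantile_used: float


def extract_bmz_mask(seg: SegmentationResult,
                     out_size: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Binary mask of the BMZ class, optionally upscaled (nearest
    neighbour) to the classification raster."""
    if seg.substrate != "esophagus":
        raise ValueError("BMZ mask extraction needs an esophagus segmentation")
    mask = seg.class_map == ESOPHAGUS_CLASSES["bmz"]
    if out_size is not None:
        mask = resize_mask_to(mask, out_size)
    return mask


def desmosome_region(seg: SegmentationResult, band_px: int = 20) -> np.ndarray:
    """Band of epithelium adjacent to the BMZ where intercellular staining
    is brightest: the BMZ mask dilated ``band_px`` times by the unit disc,
    intersected with the epithelium class (the BMZ pixels themselves are
    excluded unless labeled epithelium)."""
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    if seg.substrate != "esophagus":
        raise ValueError("desmosome region needs an esophagus segmentation")
    bmz = seg.class_map == ESOPHAGUS_CLASSES["bmz"]
    epi = seg.class_map == ESOPHAGUS_CLASSES["epithelium"]
    if not bmz.any() or not epi.any():
        return np.zeros_like(epi)
    grown = ndimage.binary_dilation(bmz, structure=np.ones((3, 3), bool),
                                    iterations=band_px)
    return grown & epi


def pattern_region(seg: SegmentationResult, pattern: str,
                   band_px: int = 20) -> np.ndarray:
    if pattern == "BMZ":
        return extract_bmz_mask(seg)
    if pattern == "intercellular":
        return desmosome_region(seg, band_px=band_px)
    raise ValueError(f"unknown esophagus pattern {pattern!r}")


def region_intensity(image: LabeledImage | np.ndarray, region: np.ndarray,
                     q: float = 0.95,
                     calibration: Sequence[tuple[float, float]] = ((0.0, 1.0), (1.0, 5.0)),
                     ) -> RegionIntensity:
    """Quantile intensity of ``region`` mapped onto the [1, 5] score scale.

    ``raw_intensity`` is the linear-interpolation ``q``-quantile of the
    pixel intensities inside the region; the score is a piecewise-linear
    map through the calibration knots (default: raw 0 -> 1, raw 1 -> 5).
    An empty region is an error — there is nothing to titer.
    """
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    region = np.asarray(region, dtype=bool)
    if region.shape != pixels.shape:
        region = resize_mask_to(region, pixels.shape)
    if not region.any():
        raise ValueError("empty region: no intensity to extract")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    raw = float(np.quantile(pixels[region], q))
    knots = sorted(calibration)
    xs = [k[0] for k in knots]
    ys = [k[1] for k in knots]
    score = float(np.interp(raw, xs, ys))
    return RegionIntensity(region=region, raw_intensity=raw, score=score,
                           quantile_used=q)


# ---------------------------------------------------------------------------
# classifier


@dataclass
class EsoNetConfig:
    hidden: tuple[int, ...] = (24, 12)
    learning_rate: float = 1e-2
    epochs: int = 60
    batch_size: int = 64
    cls_size: int = 2048
    augment_flip: bool = True
    n_augment: int = 1
    use_attention: bool = True  # False: single-input ablation variant
    seed: int = 0


@dataclass
class EsoModel:
    net: nn.MultiHeadMLP
    cls_size: int

    def save(self, path: str | Path) -> None:
        self.net.meta["cls_size"] = np.array([self.cls_size])
        self.net.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "EsoModel":
        net = nn.MultiHeadMLP.load(path)
        return cls(net=net, cls_size=int(net.meta["cls_size"][0]))


def classify_eso(model: EsoModel, image_cls: LabeledImage | np.ndarray,
                 bmz_mask_cls: np.ndarray,
                 thresholds: Optional[dict[str, float]] = None) -> EsoClassification:
    """Dual-input classification: fluorescence image plus binary BMZ mask.

    Each pattern gets an independent sigmoid probability; a pattern is
    called when its probability reaches its threshold (default 0.5 each).
    """
    pixels = image_cls.pixels if isinstance(image_cls, LabeledImage) else np.asarray(image_cls)
    mask = np.asarray(bmz_mask_cls, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError(f"image {pixels.shape} and mask {mask.shape} differ in shape")
    thresholds = thresholds or {}
    X = eso_features(pixels, mask)[None, :]
    probs = model.net.predict(X)["pattern"][0]
    prob_map = {p: float(probs[i]) for i, p in enumerate(ESO_PATTERNS)}
    calls = {p for p, v in prob_map.items() if v >= thresholds.get(p, 0.5)}
    return EsoClassification(probs=prob_map, calls=calls)


def train_eso_classifier(dataset: Sequence[tuple], seg_model: SegModel,
                         config: EsoNetConfig = EsoNetConfig()) -> EsoModel:
    """Train the dual-input classifier from (image, pattern label set) pairs.

    For every image the segmentation model produces, on the fly, the binary
    BMZ mask that focuses the feature pooling; the attention-conditioned
    features then feed a two-sigmoid-head net optimized with binary
    cross-entropy. Augmentation flips image and mask together. With
    ``config.use_attention`` off, an all-false mask replaces the BMZ mask
    (the single-input ablation: only global image statistics remain).
    """
    items = list(dataset)
    if not items:
        raise ValueError("empty esophagus training set")
    rng = np.random.default_rng(config.seed)
    size = (config.cls_size, config.cls_size)
    feats, targets = [], []
    for image, labels in items:
        pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
        labels = set(labels)
        if not labels <= set(ESO_PATTERNS):
            raise ValueError(f"unknown pattern labels {labels - set(ESO_PATTERNS)}")
        if config.use_attention:
            seg = segment(seg_model, pixels)
            mask = extract_bmz_mask(seg, out_size=size)
        else:
            mask = np.zeros(size, dtype=bool)
        img = resize_to(pixels, size).pixels
        variants = [(img, mask)]
        for _ in range(config.n_augment):
            v, m = img, mask
            if config.augment_flip:
                if rng.random() < 0.5:
                    v, m = v[::-1], m[::-1]
                if rng.random() < 0.5:
                    v, m = v[:, ::-1], m[:, ::-1]
            variants.append((v, m))
        t = [1.0 if p in labels else 0.0 for p in ESO_PATTERNS]
        for v, m in variants:
            feats.append(eso_features(v, m))
            targets.append(t)
    X = np.asarray(feats)
    y = np.asarray(targets)
    net = nn.MultiHeadMLP(
        n_in=X.shape[1], hidden=config.hidden,
        heads=[nn.HeadSpec("pattern", len(ESO_PATTERNS), "sigmoid")],
        seed=config.seed, feature_names=list(ESO_FEATURE_NAMES))
    nn.train_mlp(net, X, {"pattern": nn.HeadTask("binary_cross_entropy", y)},
                 epochs=config.epochs, batch_size=config.batch_size,
                 lr=config.learning_rate, seed=config.seed)
    return EsoModel(net=net, cls_size=config.cls_size)
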