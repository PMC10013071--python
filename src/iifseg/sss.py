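"""Salt-split-skin pipeline: attention lines, Poisson-disc patch sampling,
the two-head patch net, and the aggregation/brightness statistics.

Inference runs in four stages, separately for the epidermal roof and the
dermal floor:

1. from the 4-class segmentation, attention lines are computed by binary
   dilation algebra: ``L_roof = DIL(R) ∩ (DIL(F) ∪ DIL(I))`` and
   ``L_floor = DIL(F) ∩ (DIL(R) ∪ DIL(I))``, with DIL the Minkowski
   dilation by a disc of 3 px diameter;
2. the lines are mapped to the classification raster (4x the segmentation
   scale) and 40 patches of 64x64 px are sampled along each line by
   Poisson-disc (minimum pairwise distance) sampling, padding with empty
   patches when the line is short;
3. each patch is scored by a small two-head net: a softmax over
   {positive, negative, background, unclear} and a brightness regression
   on the [1, 5] score scale;
4. the patch results are aggregated:  y = (1 + y_pos - y_neg) / 2  with
   y_pos/y_neg the mean argmax-label probability over the patches called
   positive/negative ('background' and 'unclear' are ignored), and the
   side brightness b is the mean brightness of the three patches with the
   highest 'positive' probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.morphology import skeletonize

from . import nn
from .features import patch_features, PATCH_FEATURE_NAMES
from .imaging import LabeledImage, dilate_disc, resize_to
from .segmentation import SegmentationResult
from .synthetic import SPLIT_SKIN_CLASSES

__all__ = [
    "PATCH_LABELS", "AttentionLines", "Patch", "PatchResult", "SideResult",
    "PatchNetConfig", "PatchModel", "compute_attention_lines", "line_coords",
    "sample_patches", "classify_patches", "aggregate", "classify_side",
    "train_patch_net",
]

PATCH_LABELS = ("positive", "negative", "background", "unclear")
SIDES = ("roof", "floor")
SIDE_PATTERN = {"roof": "epidermal", "floor": "dermal"}


@dataclass
class AttentionLines:
    """Pixel sets along the split where diagnostic fluorescence occurs,
    in segmentation working coordinates; ``scale_factor`` maps them onto
    the classification raster."""

    roof_line: np.ndarray  # bool, seg working size
    floor_line: np.ndarray
    scale_factor: int = 4

    def line(self, side: str) -> np.ndarray:
        if side == "roof":
            return self.roof_line
        if side == "floor":
            return self.floor_line
        raise ValueError(f"side must be 'roof' or 'floor', got {side!r}")


@dataclass
class Patch:
    pixels: np.ndarray  # (patch_size, patch_size)
    center: tuple[int, int]  # (row, col) at classification scale
    side: str
    is_padding: bool = False


@dataclass
class PatchResult:
    label_probs: np.ndarray  # over PATCH_LABELS
    brightness: float

    def __post_init__(self):
        self.label_probs = np.asarray(self.label_probs, dtype=np.float64)
        if abs(self.label_probs.sum() - 1.0) > 1e-5:
            raise ValueError("label probabilities must sum to 1")

    @property
    def argmax_label(self) -> str:
        return PATCH_LABELS[int(np.argmax(self.label_probs))]


@dataclass
class SideResult:
    side: str
    y: float
    y_pos: float
    y_neg: float
    b: Optional[float]  # None when no patch was called positive
    n_informative: int


def compute_attention_lines(seg: SegmentationResult, dil_diameter: int = 3,
                            scale_factor: int = 4) -> AttentionLines:
    """Evaluate the two dilation-overlap set equations on a 4-class
    split-skin segmentation. Empty regions are allowed and simply yield
    empty lines."""
    if seg.substrate != "split_skin":
        raise ValueError("attention lines are defined for split-skin segmentations")
    cm = seg.class_map
    r = dilate_disc(cm == SPLIT_SKIN_CLASSES["roof"], dil_diameter)
    f = dilate_disc(cm == SPLIT_SKIN_CLASSES["floor"], dil_diameter)
    i = dilate_disc(cm == SPLIT_SKIN_CLASSES["interspace"], dil_diameter)
    return AttentionLines(roof_line=r & (f | i), floor_line=f & (r | i),
                          scale_factor=scale_factor)


def line_coords(line_mask: np.ndarray, scale_factor: int) -> np.ndarray:
    """Line pixel centres mapped to the classification raster, shape (N, 2)."""
    rr, cc = np.nonzero(line_mask)
    if len(rr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.column_stack([rr * scale_factor + scale_factor // 2,
                            cc * scale_factor + scale_factor // 2])


def estimate_line_length(line_mask: np.ndarray, scale_factor: int,
                         thickness_px: float = 3.0) -> float:
    """Arclength estimate: line pixel count divided by the nominal line
    thickness, mapped to classification scale."""
    return float(np.count_nonzero(line_mask)) / thickness_px * scale_factor


def _extract_patch(image: np.ndarray, center: tuple[int, int],
                   patch_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a fully-inside patch around ``center``, shifting inward at the
    image border; returns the (possibly shifted) centre actually used."""
    h, w = image.shape
    half = patch_size // 2
    r = int(np.clip(center[0], half, h - (patch_size - half)))
    c = int(np.clip(center[1], half, w - (patch_size - half)))
    return image[r - half:r - half + patch_size,
                 c - half:c - half + patch_size].copy(), (r, c)


def sample_patches(image_cls: np.ndarray, line: np.ndarray | AttentionLines,
                   side: str = "roof", n_target: int = 40, patch_size: int = 64,
                   radius: Optional[float] = None, seed: int = 0,
                   scale_factor: int = 4) -> list[Patch]:
    """Poisson-disc sampling of patches along an attention line.

    Candidate centres are the line's medial axis (the attention line is a
    few pixels thick; its skeleton keeps patch centres laterally true),
    visited in seeded random order and accepted when at least ``radius``
    away from every accepted centre (dart throwing). The default radius is
    the estimated line length divided by ``n_target + 1``, clamped to
    [8, 64] px at classification scale. The output always contains exactly
    ``n_target`` patches; missing ones are empty padding patches, mirroring
    the fixed-count training convention.
    """
    if isinstance(line, AttentionLines):
        mask = line.line(side)
        scale_factor = line.scale_factor
    else:
        mask = np.asarray(line, dtype=bool)
    skel = skeletonize(mask) if mask.any() else mask
    coords = line_coords(skel, scale_factor)
    if radius is None:
        length = float(skel.sum()) * scale_factor
        radius = float(np.clip(length / (n_target + 1), 8.0, 64.0))
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    if len(coords):
        order = rng.permutation(len(coords))
        acc = np.empty((0, 2))
        for idx in order:
            p = coords[idx].astype(float)
            if len(acc) == 0 or (np.hypot(*(acc - p).T) >= radius).all():
                acc = np.vstack([acc, p])
                accepted.append(coords[idx])
                if len(accepted) >= n_target:
                    break
    patches = []
    for center in accepted:
        pix, used_center = _extract_patch(image_cls, tuple(center), patch_size)
        patches.append(Patch(pixels=pix, center=used_center, side=side))
    while len(patches) < n_target:
        patches.append(Patch(pixels=np.zeros((patch_size, patch_size)),
                             center=(-1, -1), side=side, is_padding=True))
    return patches


# ---------------------------------------------------------------------------
# patch net


@dataclass
class PatchNetConfig:
    hidden: tuple[int, ...] = (24, 12)
    learning_rate: float = 1e-2
    epochs: int = 40
    batch_size: int = 128
    augment_flip: bool = True
    augment_noise_sd: float = 0.02
    n_augment: int = 1
    seed: int = 0


@dataclass
class PatchModel:
    net: nn.MultiHeadMLP
    side: str
    # operating point on the aggregated score y; 0.5 until calibrated on
    # labeled data (the threshold travels with the model)
    threshold: float = 0.5

    def save(self, path: str | Path) -> None:
        self.net.meta["side"] = np.array(self.side)
        self.net.meta["threshold"] = np.array([self.threshold])
        self.net.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "PatchModel":
        net = nn.MultiHeadMLP.load(path)
        threshold = float(net.meta.get("threshold", np.array([0.5]))[0])
        return cls(net=net, side=str(net.meta["side"]), threshold=threshold)


def train_patch_net(patch_dataset: Sequence[tuple], side: str,
                    config: PatchNetConfig = PatchNetConfig()) -> PatchModel:
    """Train one side's patch net on (pixels, label, brightness) triples.

    The loss is categorical cross-entropy on the label head plus mean
    squared error on the brightness head, weighted equally; brightness
    targets only contribute for patches whose label carries one (positive
    and negative tissue patches). Augmentation: horizontal/vertical patch
    flips and additive Gaussian noise.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    items = list(patch_dataset)
    if not items:
        raise ValueError("empty patch dataset")
    rng = np.random.default_rng(config.seed)
    feats, labels, targets = [], [], []
    for pixels, label, brightness in items:
        if label not in PATCH_LABELS:
            raise ValueError(f"unknown patch label {label!r}")
        variants = [np.asarray(pixels, dtype=np.float64)]
        for _ in range(config.n_augment):
            v = variants[0]
            if config.augment_flip:
                if rng.random() < 0.5:
                    v = v[::-1]
                if rng.random() < 0.5:
                    v = v[:, ::-1]
            if config.augment_noise_sd > 0:
                v = np.clip(v + rng.normal(0, config.augment_noise_sd, v.shape), 0, 1)
            variants.append(v)
        for v in variants:
            feats.append(patch_features(v))
            labels.append(PATCH_LABELS.index(label))
            targets.append(brightness if brightness is not None else np.nan)
    X = np.asarray(feats)
    y_onehot = np.eye(len(PATCH_LABELS))[np.asarray(labels)]
    t = np.asarray(targets, dtype=np.float64)
    bright_w = np.isfinite(t).astype(np.float64)
    t = np.nan_to_num(t, nan=0.0).reshape(-1, 1)

    net = nn.MultiHeadMLP(
        n_in=X.shape[1], hidden=config.hidden,
        heads=[nn.HeadSpec("label", len(PATCH_LABELS), "softmax"),
               nn.HeadSpec("brightness", 1, "linear")],
        seed=config.seed, feature_names=list(PATCH_FEATURE_NAMES))
    nn.train_mlp(
        net, X,
        {"label": nn.HeadTask("categorical_cross_entropy", y_onehot, loss_weight=1.0),
         "brightness": nn.HeadTask("mse", t, sample_weight=bright_w, loss_weight=1.0)},
        epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, seed=config.seed)
    return PatchModel(net=net, side=side)


def classify_patches(model: PatchModel, patches: Sequence[Patch]) -> list[PatchResult]:
    """Score every patch (padding included — training labels them
    'background', so they fall out of the aggregation)."""
    if not patches:
        return []
    X = np.asarray([patch_features(p.pixels) for p in patches])
    out = model.net.predict(X)
    probs = out["label"]
    bright = out["brightness"][:, 0]
    return [PatchResult(label_probs=probs[i], brightness=float(bright[i]))
            for i in range(len(patches))]


def aggregate(results: Sequence[PatchResult], side: str = "roof") -> SideResult:
    """Aggregate patch results into the side-level score and brightness.

    ``N``/``P`` collect the patches whose argmax label is negative/positive;
    ``f(x_i)`` is the probability of that argmax label. An empty ``N`` or
    ``P`` contributes 0 to its term, so no informative patch at all gives
    y = 0.5. Brightness ``b`` is the mean over the (up to) three positive
    patches with the highest 'positive' probability, and is undefined
    (None) when no patch is positive.
    """
    pos_idx = [i for i, r in enumerate(results) if r.argmax_label == "positive"]
    neg_idx = [i for i, r in enumerate(results) if r.argmax_label == "negative"]
    y_pos = float(np.mean([results[i].label_probs[0] for i in pos_idx])) if pos_idx else 0.0
    y_neg = float(np.mean([results[i].label_probs[1] for i in neg_idx])) if neg_idx else 0.0
    y = (1.0 + y_pos - y_neg) / 2.0
    if pos_idx:
        top3 = sorted(pos_idx, key=lambda i: results[i].label_probs[0],
                      reverse=True)[:3]
        b = float(np.mean([results[i].brightness for i in top3]))
    else:
        b = None
    return SideResult(side=side, y=y, y_pos=y_pos, y_neg=y_neg, b=b,
                      n_informative=len(pos_idx) + len(neg_idx))


def classify_side(image: LabeledImage | np.ndarray, seg: SegmentationResult,
                  model: PatchModel, side: str,
                  threshold: Optional[float] = None,
                  n_target: int = 40, patch_size: int = 64, seed: int = 0,
                  scale_factor: int = 4) -> tuple[str, SideResult]:
    """Run the composed per-side inference: attention line -> patches ->
    patch net -> aggregation -> call.

    The call is positive iff ``y >= threshold`` (ties go to positive) and
    at least one patch was called positive — a side without any positive
    patch cannot be titered and is reported negative regardless of y.
    ``threshold=None`` uses the model's stored operating point.
    """
    if threshold is None:
        threshold = model.threshold
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    lines = compute_attention_lines(seg, scale_factor=scale_factor)
    cls_size = seg.working_size[0] * scale_factor
    image_cls = resize_to(pixels, (cls_size, cls_size)).pixels
    patches = sample_patches(image_cls, lines, side=side, n_target=n_target,
                             patch_size=patch_size, seed=seed)
    results = classify_patches(model, patches)
    side_result = aggregate(results, side=side)
    call = "positive" if (side_result.y >= threshold and side_result.b is not None) \
        else "negative"
    return call, side_result
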