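"""Semantic segmentation of both tissue substrates.

The segmenter is a per-pixel classifier: a multiscale filter bank
(:mod:`iifseg.features`) feeds a small multi-head perceptron that assigns
each pixel one of the substrate's classes — roof/floor/interspace/background
for salt-split skin, the seven esophagus layers otherwise. Training uses
Adam with the generalized Dice loss for split skin (robust to the thin,
imbalanced regions) and categorical cross-entropy for esophagus, with
flip/rotation/zoom augmentation applied to image and mask together.

Inference accepts any input size; images are resampled to the working
resolution (default 512x512) and the result stays in working coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .features import pixel_features, PIXEL_FEATURE_NAMES
from .imaging import LabeledImage, load_green, load_mask_png, resize_to, resize_mask_to
from .synthetic import SUBSTRATE_CLASSES

__all__ = [
    "SegModelConfig", "SegmentationResult", "SegModel",
    "train_segmenter", "segment", "generalized_dice_loss", "dice_per_class",
]

# re-exported: the published loss evaluated on probability arrays
generalized_dice_loss = nn.generalized_dice_loss

_DEFAULT_LOSS = {"split_skin": "generalized_dice",
                 "esophagus": "categorical_cross_entropy"}


@dataclass
class SegModelConfig:
    substrate: str
    working_size: int = 512
    hidden: tuple[int, ...] = (32, 16)
    loss: Optional[str] = None  # default chosen per substrate
    learning_rate: float = 1e-2
    adam_betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 12
    batch_size: int = 2048
    pixels_per_image: int = 3000
    augment_flip: bool = True
    augment_rotation: bool = True
    augment_zoom: bool = False
    n_augment: int = 1
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.substrate not in SUBSTRATE_CLASSES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.loss is None:
            self.loss = _DEFAULT_LOSS[self.substrate]
        if self.loss not in ("generalized_dice", "categorical_cross_entropy"):
            raise ValueError(f"unsupported segmentation loss {self.loss!r}")

    @property
    def n_classes(self) -> int:
        return len(SUBSTRATE_CLASSES[self.substrate])


@dataclass
class SegmentationResult:
    """Per-pixel class probabilities and their argmax labels at working size."""

    class_probs: np.ndarray  # (H, W, C)
    class_map: np.ndarray  # (H, W) int
    working_size: tuple[int, int]
    substrate: str

    def __post_init__(self):
        s = self.class_probs.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("class probabilities must sum to 1 at every pixel")


@dataclass
class SegModel:
    net: nn.MultiHeadMLP
    substrate: str
    working_size: int
    # spatial regularization: per-class probability maps are blurred with
    # this Gaussian sigma (px at working scale) before the argmax, removing
    # the salt-and-pepper errors a purely local classifier produces
    smooth_sigma: float = 1.5
    train_history: list = field(default_factory=list)

    @property
    def classes(self) -> dict[str, int]:
        return SUBSTRATE_CLASSES[self.substrate]

    def save(self, path: str | Path) -> None:
        self.net.meta["substrate"] = np.array(self.substrate)
        self.net.meta["working_size"] = np.array([self.working_size])
        self.net.meta["smooth_sigma"] = np.array([self.smooth_sigma])
        self.net.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        net = nn.MultiHeadMLP.load(path)
        return cls(net=net, substrate=str(net.meta["substrate"]),
                   working_size=int(net.meta["working_size"][0]),
                   smooth_sigma=float(net.meta["smooth_sigma"][0]))


def augment_pair(pixels: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 config: SegModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """One random geometric augmentation applied to image and mask together.

    Rotation angle is uniform in [0, 360); zoom factor uniform in [0.9, 1.1].
    Intensities are interpolated bilinearly, labels nearest-neighbour.
    """
    img, msk = pixels, mask
    if config.augment_flip:
        if rng.random() < 0.5:
            img, msk = img[::-1], msk[::-1]
        if rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]
    if config.augment_rotation:
        angle = float(rng.uniform(0.0, 360.0))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="reflect")
    if config.augment_zoom:
        z = float(rng.uniform(0.9, 1.1))
        h, w = img.shape
        img = np.clip(resize_to(np.clip(img, 0, 1), (max(8, int(h * z)), max(8, int(w * z)))).pixels, 0, 1)
        msk = resize_mask_to(msk, img.shape)
        img = np.clip(resize_to(img, (h, w)).pixels, 0, 1)
        msk = resize_mask_to(msk, (h, w))
    return np.ascontiguousarray(np.clip(img, 0.0, 1.0)), np.ascontiguousarray(msk)


DatasetLike = Union[str, Path, pd.DataFrame, Sequence[tuple]]


def _load_pairs(dataset: DatasetLike) -> list[tuple[np.ndarray, np.ndarray]]:
    """Accept a manifest CSV path, a manifest DataFrame, or in-memory
    (image, mask) pairs; return raw (pixels, mask) tuples."""
    if isinstance(dataset, (str, Path)):
        dataset = pd.read_csv(dataset)
    pairs = []
    if isinstance(dataset, pd.DataFrame):
        if dataset.empty:
            raise ValueError("empty dataset manifest")
        for _, row in dataset.iterrows():
            img = load_green(row["image_path"])
            mask = load_mask_png(row["mask_path"])
            pairs.append((img.pixels, mask))
        return pairs
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    for img, mask in dataset:
        pixels = img.pixels if isinstance(img, LabeledImage) else np.asarray(img)
        mask = mask.seg_mask if hasattr(mask, "seg_mask") else np.asarray(mask)
        pairs.append((pixels, mask))
    return pairs


def _pixel_samples(pixels: np.ndarray, mask: np.ndarray, config: SegModelConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified pixel sampling of one (image, mask) pair at working
    resolution; returns (features, one-hot labels)."""
    size = (config.working_size, config.working_size)
    img = resize_to(pixels, size).pixels
    msk = resize_mask_to(mask, size)
    feats = pixel_features(img)
    n_classes = config.n_classes
    present = [c for c in range(n_classes) if (msk == c).any()]
    per_class = max(config.pixels_per_image // max(len(present), 1), 1)
    rows_all, cols_all = [], []
    for c in present:
        rr, cc = np.nonzero(msk == c)
        take = min(per_class, len(rr))
        pick = rng.choice(len(rr), size=take, replace=False)
        rows_all.append(rr[pick])
        cols_all.append(cc[pick])
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    X = feats[rows, cols]
    y = np.eye(n_classes)[msk[rows, cols]]
    return X, y


def train_segmenter(dataset: DatasetLike, config: SegModelConfig) -> SegModel:
    """Train the per-pixel segmenter; deterministic for a fixed config seed.

    A validation split is held out to confirm the loss decreased relative to
    the zero-initialized (uniform-probability) starting point; the initial
    and final validation losses are stored in the model metadata.
    """
    pairs = _load_pairs(dataset)
    for _, mask in pairs:
        if mask.max(initial=0) >= config.n_classes:
            raise ValueError("mask labels exceed the substrate's class count")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(len(pairs) * config.val_fraction))
    order = rng.permutation(len(pairs))
    val_idx = set(order[:n_val].tolist())

    Xs, ys, Xv, yv = [], [], [], []
    for i, (pixels, mask) in enumerate(pairs):
        variants = [(pixels, mask)]
        if i not in val_idx:
            for _ in range(config.n_augment):
                variants.append(augment_pair(pixels, mask, rng, config))
        for px, mk in variants:
            X, y = _pixel_samples(px, mk, config, rng)
            if i in val_idx:
                Xv.append(X)
                yv.append(y)
            else:
                Xs.append(X)
                ys.append(y)
    X = np.concatenate(Xs)
    y = np.concatenate(ys)

    net = nn.MultiHeadMLP(
        n_in=X.shape[1], hidden=config.hidden,
        heads=[nn.HeadSpec("label", config.n_classes, "softmax")],
        seed=config.seed, feature_names=list(PIXEL_FEATURE_NAMES))
    net.set_normalization(X)

    loss_fn = nn.LOSSES[config.loss]
    if Xv:
        Xv = np.concatenate(Xv)
        yv = np.concatenate(yv)
        val0 = loss_fn(net.forward(Xv)["label"], yv)[0]
    history = nn.train_mlp(
        net, X, {"label": nn.HeadTask(config.loss, y)},
        epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, seed=config.seed, set_normalization=False)
    model = SegModel(net=net, substrate=config.substrate,
                     working_size=config.working_size, train_history=history)
    if len(Xv):
        val1 = loss_fn(net.forward(Xv)["label"], yv)[0]
        net.meta["val_loss_init"] = np.array([val0])
        net.meta["val_loss_final"] = np.array([val1])
    return model


def segment(model: SegModel, image: LabeledImage | np.ndarray) -> SegmentationResult:
    """Segment an image of any size at the model's working resolution."""
    if isinstance(image, LabeledImage):
        if image.substrate is not None and image.substrate != model.substrate:
            raise ValueError(
                f"model is for {model.substrate!r} but image is {image.substrate!r}")
        pixels = image.pixels
    else:
        pixels = np.asarray(image, dtype=np.float64)
    size = (model.working_size, model.working_size)
    work = resize_to(pixels, size).pixels
    feats = pixel_features(work)
    flat = feats.reshape(-1, feats.shape[-1])
    probs = np.empty((flat.shape[0], len(model.classes)))
    chunk = 1 << 16
    for start in range(0, flat.shape[0], chunk):
        probs[start:start + chunk] = model.net.predict(flat[start:start + chunk])["label"]
    probs = probs.reshape(size + (len(model.classes),))
    if model.smooth_sigma > 0:
        probs = ndimage.gaussian_filter(probs, (model.smooth_sigma, model.smooth_sigma, 0))
        probs /= probs.sum(axis=-1, keepdims=True)
    return SegmentationResult(class_probs=probs,
                              class_map=np.argmax(probs, axis=-1),
                              working_size=size, substrate=model.substrate)


def dice_per_class(pred_map: np.ndarray, true_map: np.ndarray,
                   n_classes: int) -> np.ndarray:
    """Soerensen-Dice coefficient per class; NaN for classes absent from
    both prediction and reference."""
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        p = pred_map == c
        t = true_map == c
        denom = p.sum() + t.sum()
        if denom > 0:
            out[c] = 2.0 * np.logical_and(p, t).sum() / denom
    return out
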