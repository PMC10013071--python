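"""Builders that turn labeled scenes into training sets for the three nets.

Scenes are (image, ground-truth) pairs — from the synthetic generator or
from any manifest with masks and pattern labels. Patch labels for the
salt-split-skin nets are derived from the ground-truth geometry: patches on
the attention line inherit the image's side label (positive with the
image's brightness score, else negative), deep-background patches and empty
padding patches are 'background', and patches from tissue interior far from
the split are 'unclear' (they carry no decision-relevant information).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging import LabeledImage, dilate_disc
from .synthetic import SPLIT_SKIN_CLASSES, GroundTruth
from .sss import SIDE_PATTERN, sample_patches, _extract_patch

__all__ = ["truth_attention_line", "build_sss_patch_dataset", "build_eso_dataset"]


def truth_attention_line(seg_mask: np.ndarray, side: str,
                         dil_diameter: int = 3) -> np.ndarray:
    """Attention line evaluated on a ground-truth split-skin mask."""
    r = dilate_disc(seg_mask == SPLIT_SKIN_CLASSES["roof"], dil_diameter)
    f = dilate_disc(seg_mask == SPLIT_SKIN_CLASSES["floor"], dil_diameter)
    i = dilate_disc(seg_mask == SPLIT_SKIN_CLASSES["interspace"], dil_diameter)
    return r & (f | i) if side == "roof" else f & (r | i)


def _interior_centers(region: np.ndarray, margin: float,
                      rng: np.random.Generator, k: int) -> list[tuple[int, int]]:
    dist = ndimage.distance_transform_edt(region)
    rr, cc = np.nonzero(dist > margin)
    if len(rr) == 0:
        return []
    pick = rng.choice(len(rr), size=min(k, len(rr)), replace=False)
    return [(int(rr[j]), int(cc[j])) for j in pick]


def build_sss_patch_dataset(scenes: Sequence[tuple[LabeledImage, GroundTruth]],
                            side: str, n_line: int = 12, n_background: int = 3,
                            n_unclear: int = 3, n_padding: int = 1,
                            patch_size: int = 64, jitter_px: int = 6,
                            seed: int = 0
                            ) -> list[tuple[np.ndarray, str, Optional[float]]]:
    """(pixels, label, brightness score) triples for one side's patch net.

    Patches are cut at the scene's native resolution, which plays the role
    of the classification raster. Centres are jittered by up to
    ``jitter_px`` in each axis: at inference the attention line comes from
    a segmentation at quarter resolution, so patch centres land a few
    pixels off the true line and the net must tolerate that. Brightness
    targets exist only for tissue patches: the image's score for
    positives, the scale floor 1.0 for negatives, none for
    background/unclear.
    """
    rng = np.random.default_rng(seed)
    pattern = SIDE_PATTERN[side]
    out: list[tuple[np.ndarray, str, Optional[float]]] = []
    for image, gt in scenes:
        pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
        line = truth_attention_line(gt.seg_mask, side)
        # where roof and floor stay attached, either binding shows the same
        # junction fluorescence: those stretches carry no side information
        # and are taught as 'unclear' (readers rely on the detached split)
        attached = (dilate_disc(gt.seg_mask == SPLIT_SKIN_CLASSES["roof"], 3)
                    & dilate_disc(gt.seg_mask == SPLIT_SKIN_CLASSES["floor"], 3))
        detached = line & ~attached
        positive = pattern in gt.pattern_labels
        score = gt.brightness.get(pattern) if positive else 1.0
        def _jittered(center):
            dr, dc = rng.integers(-jitter_px, jitter_px + 1, size=2)
            return (int(center[0] + dr), int(center[1] + dc))

        for p in sample_patches(pixels, detached, side=side, n_target=n_line,
                                patch_size=patch_size, scale_factor=1,
                                seed=int(rng.integers(1 << 31))):
            if p.is_padding:
                continue
            pix, _ = _extract_patch(pixels, _jittered(p.center), patch_size)
            out.append((pix, "positive" if positive else "negative", score))
        for p in sample_patches(pixels, line & dilate_disc(attached, 3),
                                side=side, n_target=max(2, n_line // 4),
                                patch_size=patch_size, scale_factor=1,
                                seed=int(rng.integers(1 << 31))):
            if not p.is_padding:
                pix, _ = _extract_patch(pixels, _jittered(p.center), patch_size)
                out.append((pix, "unclear", None))
        # patches that miss the line by more than the jitter tolerance see
        # any staining off-centre: ambiguous, so taught as 'unclear'
        for p in sample_patches(pixels, detached, side=side,
                                n_target=max(2, n_line // 3),
                                patch_size=patch_size, scale_factor=1,
                                seed=int(rng.integers(1 << 31))):
            if p.is_padding:
                continue
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(jitter_px + 4, 24)
            center = (int(p.center[0] + off * np.sin(ang)),
                      int(p.center[1] + off * np.cos(ang)))
            pix, _ = _extract_patch(pixels, center, patch_size)
            out.append((pix, "unclear", None))
        margin = patch_size * 0.7
        bg = gt.seg_mask == SPLIT_SKIN_CLASSES["background"]
        for center in _interior_centers(bg, margin, rng, n_background):
            pix, _ = _extract_patch(pixels, center, patch_size)
            out.append((pix, "background", None))
        for _ in range(n_padding):
            out.append((np.zeros((patch_size, patch_size)), "background", None))
        interior = ((gt.seg_mask == SPLIT_SKIN_CLASSES["roof"]) |
                    (gt.seg_mask == SPLIT_SKIN_CLASSES["floor"])) & ~dilate_disc(line, 9)
        for center in _interior_centers(interior, margin, rng, n_unclear):
            pix, _ = _extract_patch(pixels, center, patch_size)
            out.append((pix, "unclear", None))
    return out


def build_eso_dataset(scenes: Sequence[tuple[LabeledImage, GroundTruth]]
                      ) -> list[tuple[LabeledImage, set[str]]]:
    """(image, active pattern set) pairs for the esophagus classifier."""
    return [(image, set(gt.pattern_labels)) for image, gt in scenes]
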