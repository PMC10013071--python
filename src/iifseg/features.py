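"""Engineered image features feeding the trainable components.

Three feature families:

* per-pixel multiscale filter-bank features for the tissue segmenters
  (Gaussian pyramid, difference-of-Gaussians, gradient magnitude, local
  standard deviation, and a wide-context mean that separates the dark
  interspace inside the tissue band from far background);
* summary features of a 64x64 patch for the salt-split-skin patch net,
  built to respond to a thin bright line crossing the patch centre;
* attention-conditioned features for the esophagus classifier, pooling
  intensities inside the basement-membrane mask, in a ring around it, and
  globally, plus a mesh-energy statistic for intercellular staining.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor, structure_tensor_eigenvalues

__all__ = [
    "pixel_features",
    "PIXEL_FEATURE_NAMES",
    "patch_features",
    "PATCH_FEATURE_NAMES",
    "eso_features",
    "ESO_FEATURE_NAMES",
]

_SIGMAS = (1.0, 2.0, 4.0, 8.0, 16.0)

PIXEL_FEATURE_NAMES = (
    ["intensity"]
    + [f"gauss_{s:g}" for s in _SIGMAS]
    + [f"dog_{a:g}_{b:g}" for a, b in zip(_SIGMAS[:-1], _SIGMAS[1:])]
    + ["grad_1", "grad_4", "local_std_2", "context_24",
       "coherence_2", "coherence_5", "surround_min_12", "surround_max_12"]
)


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, F)."""
    img = np.asarray(pixels, dtype=np.float64)
    gs = [ndimage.gaussian_filter(img, s) for s in _SIGMAS]
    feats = [img] + gs
    feats += [a - b for a, b in zip(gs[:-1], gs[1:])]
    feats.append(ndimage.gaussian_gradient_magnitude(img, 1.0))
    feats.append(ndimage.gaussian_gradient_magnitude(img, 4.0))
    m2 = ndimage.gaussian_filter(img, 2.0)
    sq2 = ndimage.gaussian_filter(img ** 2, 2.0)
    feats.append(np.sqrt(np.clip(sq2 - m2 ** 2, 0.0, None)))
    feats.append(ndimage.gaussian_filter(img, 24.0))
    # structure-tensor coherence: rotation-invariant texture anisotropy
    # (fibrous dermis/muscle vs cellular epidermis/epithelium)
    for sigma in (2.0, 5.0):
        A = structure_tensor(img, sigma=sigma, mode="reflect")
        l1, l2 = structure_tensor_eigenvalues(A)
        feats.append((l1 - l2) / (l1 + l2 + 1e-12))
    # surround context: blurred intensity sampled 12 px away in eight
    # directions. A dark gap *between* tissues (the interspace) keeps a
    # high minimum; dark background outside the tissue band does not.
    g4 = gs[2]
    d = 12
    shifted = []
    for dy, dx in ((d, 0), (-d, 0), (0, d), (0, -d),
                   (9, 9), (9, -9), (-9, 9), (-9, -9)):
        shifted.append(ndimage.shift(g4, (dy, dx), order=1, mode="nearest"))
    stack = np.stack(shifted)
    feats.append(stack.min(axis=0))
    feats.append(stack.max(axis=0))
    return np.stack(feats, axis=-1)


PATCH_FEATURE_NAMES = [
    "mean", "std", "q10", "q50", "q90", "q99", "smooth_max",
    "row_profile_max", "col_profile_max", "center_minus_outer",
    "bright_frac", "grad_mean", "grad_q90", "tissue_frac",
    "center_q95_minus_q50", "line_response", "row_peak_offset", "col_peak_offset",
]


def patch_features(patch: np.ndarray) -> np.ndarray:
    """Summary feature vector of a square intensity patch.

    The patch net sees patches centred on the attention line, so a specific
    reaction shows up as a thin bright band through the patch centre: the
    row/column profile maxima and the centre-vs-outer contrast carry most
    of the signal; quantiles and gradient statistics capture overall
    luminance and texture (mesh/speckle confounders).
    """
    p = np.asarray(patch, dtype=np.float64)
    n = p.shape[0]
    sm = ndimage.gaussian_filter(p, 1.0)
    q10, q50, q90, q99 = np.quantile(p, [0.10, 0.50, 0.90, 0.99])
    c = n // 2
    center = p[c - n // 4:c + n // 4, c - n // 4:c + n // 4]
    inner = p[c - n // 8:c + n // 8, c - n // 8:c + n // 8]
    outer_mean = (p.sum() - center.sum()) / max(p.size - center.size, 1)
    grad = ndimage.gaussian_gradient_magnitude(p, 1.0)
    row_prof = sm.mean(axis=1)
    col_prof = sm.mean(axis=0)
    return np.array([
        p.mean(), p.std(), q10, q50, q90, q99, sm.max(),
        row_prof.max(), col_prof.max(),
        center.mean() - outer_mean,
        float((p > q50 + 0.15).mean()),
        grad.mean(), np.quantile(grad, 0.90),
        float((p > 0.08).mean()),
        float(np.quantile(center, 0.95) - q50),
        float(np.quantile(inner, 0.9) - q50),
        # a genuine reaction line crosses the patch centre; a neighbouring
        # structure peaks off-centre
        abs(int(np.argmax(row_prof)) - n / 2) / n,
        abs(int(np.argmax(col_prof)) - n / 2) / n,
    ])


ESO_FEATURE_NAMES = [
    "bmz_q50", "bmz_q90", "bmz_q95", "bmz_q99", "bmz_frac",
    "ring_q50", "ring_q90", "ring_q99", "ring_grad_q90", "ring_mesh_frac",
    "ring_largest_cc_frac", "bmz_contrast", "ring_contrast",
    "global_q50", "global_q90", "global_q99", "global_grad_q90",
]


def eso_features(pixels: np.ndarray, bmz_mask: np.ndarray,
                 ring_px: int = 12) -> np.ndarray:
    """Attention-conditioned features for the dual-input classifier.

    ``bmz_mask`` focuses the pooling: statistics inside the mask detect
    linear BMZ staining; a ring extending ``ring_px`` (Chebyshev) to either
    side of the mask covers the adjacent epithelium where the intercellular
    mesh is brightest. With an empty mask only the global statistics carry
    information (the single-input ablation passes an all-false mask).
    """
    img = np.asarray(pixels, dtype=np.float64)
    mask = np.asarray(bmz_mask, dtype=bool)
    grad = ndimage.gaussian_gradient_magnitude(img, 1.5)
    g50, g90, g99 = np.quantile(img, [0.5, 0.9, 0.99])
    gg90 = np.quantile(grad, 0.9)

    def _region_stats(region: np.ndarray, n_quant: list[float]) -> list[float]:
        if region.any():
            vals = img[region]
            return list(np.quantile(vals, n_quant))
        return [0.0] * len(n_quant)

    bmz_q = _region_stats(mask, [0.5, 0.9, 0.95, 0.99])
    if mask.any():
        ring = ndimage.binary_dilation(mask, iterations=ring_px) & ~mask
    else:
        ring = np.zeros_like(mask)
    ring_q = _region_stats(ring, [0.5, 0.9, 0.99])
    if ring.any():
        rg = grad[ring]
        ring_grad_q90 = float(np.quantile(rg, 0.9))
        rvals = img[ring]
        thr = np.median(rvals) + 0.12
        mesh_frac = float((rvals > thr).mean())
        # intercellular staining is one connected cell-border network while
        # nuclear speckles fragment into many small components: the largest
        # connected component's share of the bright pixels separates them
        bright = (img > thr) & ring
        if bright.any():
            lab, n = ndimage.label(bright)
            sizes = np.bincount(lab.ravel())[1:]
            blob_frac = float(sizes.max() / max(bright.sum(), 1))
        else:
            blob_frac = 0.0
    else:
        ring_grad_q90, mesh_frac, blob_frac = 0.0, 0.0, 0.0
    bmz_contrast = bmz_q[1] - ring_q[0] if mask.any() else 0.0
    ring_contrast = ring_q[1] - g50 if ring.any() else 0.0
    return np.array(bmz_q + [float(mask.mean())] + ring_q
                    + [ring_grad_q90, mesh_frac, blob_frac,
                       bmz_contrast, ring_contrast, g50, g90, g99, gg90])
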