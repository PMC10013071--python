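"""Seeded synthetic IIF scenes for both tissue substrates, with exact ground
truth.

The generator emulates what the real slides show at desk scale:

* **salt-split skin** — a tissue band split into an epidermal roof and a
  dermal floor by an artificial cleft; a fraction of the split remains
  attached (configurable, default 0.3). Specific reactions render as a thin
  linear fluorescence along the roof-side ("epidermal") or floor-side
  ("dermal") boundary of the split.
* **monkey esophagus** — seven stacked layers (epithelium, thin basement
  membrane zone, lamina propria, muscular mucosa, circular muscle,
  longitudinal muscle, background) with wavy boundaries and per-layer
  autofluorescence. "BMZ" reactions brighten the BMZ line; "intercellular"
  reactions render a Voronoi cell-border mesh inside the epithelium.

Confounders (nuclear speckles inside the epithelium/epidermis, diffuse
unspecific glow) are always labeled negative for the disease patterns.
``noise_sd`` scales every stochastic intensity component — additive noise,
tissue texture and the multiplicative shading field — so ``noise_sd=0``
renders a noise-free, texture-free scene for analytic checks.

Identical ``(SceneSpec, seed)`` pairs reproduce byte-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import LabeledImage, dilate_disc, save_gray, save_mask_png

__all__ = [
    "SPLIT_SKIN_CLASSES", "ESOPHAGUS_CLASSES", "SUBSTRATE_CLASSES",
    "SUBSTRATE_PATTERNS", "SceneSpec", "GroundTruth",
    "generate_image", "generate_dilution_series", "generate_dataset",
    "GenConfig", "brightness_to_score", "score_to_brightness",
]

SPLIT_SKIN_CLASSES = {"background": 0, "roof": 1, "floor": 2, "interspace": 3}
ESOPHAGUS_CLASSES = {
    "background": 0, "longitudinal_muscle": 1, "circular_muscle": 2,
    "muscular_mucosa": 3, "bmz": 4, "lamina_propria": 5, "epithelium": 6,
}
SUBSTRATE_CLASSES = {"split_skin": SPLIT_SKIN_CLASSES,
                     "esophagus": ESOPHAGUS_CLASSES}
SUBSTRATE_PATTERNS = {"split_skin": ("epidermal", "dermal"),
                      "esophagus": ("BMZ", "intercellular")}
CONFOUNDERS = ("none", "nuclear_speckle", "diffuse_unspecific")

# baseline (autofluorescence) intensity per class
_SSS_BASE = {"background": 0.02, "roof": 0.30, "floor": 0.22, "interspace": 0.04}
_ESO_BASE = {"background": 0.02, "longitudinal_muscle": 0.28,
             "circular_muscle": 0.19, "muscular_mucosa": 0.35,
             "bmz": 0.32, "lamina_propria": 0.24, "epithelium": 0.15}
# per-class texture correlation lengths (row, col); the dermal floor and
# the muscle layers are fibrous (strongly anisotropic), the epidermis and
# epithelium are cellular (isotropic)
_TEXTURE_SIGMA = {"roof": (2.0, 2.0), "floor": (0.8, 7.0),
                  "longitudinal_muscle": (0.8, 6.0),
                  "circular_muscle": (1.5, 1.5), "muscular_mucosa": (2.5, 2.5),
                  "bmz": (2.0, 2.0), "lamina_propria": (1.0, 1.0),
                  "epithelium": (3.0, 3.0)}
_PATTERN_AMP = 0.55  # added intensity of a fully bright (beta=1) reaction


def brightness_to_score(beta: float) -> float:
    """Map generator brightness beta in [0,1] to the score scale [1,5]."""
    return 1.0 + 4.0 * float(beta)


def score_to_brightness(score: float) -> float:
    return (float(score) - 1.0) / 4.0


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene."""

    substrate: str
    pattern: str = "none"  # none | <pattern> | both
    pattern_brightness: Union[float, tuple] = 0.8
    confounder: str = "none"
    geometry_seed: int = 0
    noise_sd: float = 0.02
    output_size: tuple[int, int] = (1024, 1024)
    attachment_fraction: float = 0.3  # split-skin only

    def __post_init__(self):
        if self.substrate not in SUBSTRATE_CLASSES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        valid = ("none", "both") + SUBSTRATE_PATTERNS[self.substrate]
        if self.pattern not in valid:
            raise ValueError(
                f"pattern {self.pattern!r} invalid for {self.substrate}; "
                f"expected one of {valid}")
        if self.confounder not in CONFOUNDERS:
            raise ValueError(f"unknown confounder {self.confounder!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h, w = self.output_size
        if h < 256 or w < 256:
            raise ValueError("output_size must be at least 256x256")

    def active_brightness(self) -> dict[str, float]:
        """Brightness beta per active pattern (empty dict when negative)."""
        pats = SUBSTRATE_PATTERNS[self.substrate]
        if self.pattern == "none":
            return {}
        if self.pattern == "both":
            if isinstance(self.pattern_brightness, (tuple, list)):
                b = dict(zip(pats, self.pattern_brightness))
            else:
                b = {p: float(self.pattern_brightness) for p in pats}
        else:
            b = {self.pattern: float(self.pattern_brightness)
                 if not isinstance(self.pattern_brightness, (tuple, list))
                 else float(self.pattern_brightness[0])}
        for p, v in b.items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"active pattern {p} needs brightness in (0,1], got {v}")
        return b


@dataclass
class GroundTruth:
    """Exact per-pixel and per-pattern truth of a rendered scene."""

    seg_mask: np.ndarray  # integer labels, substrate class table
    pattern_labels: set[str]
    brightness: dict[str, float]  # score in [1,5] per active pattern
    pattern_masks: dict[str, np.ndarray] = field(default_factory=dict)
    substrate: str = ""


def _smooth_curve(rng: np.random.Generator, n: int, amp: float, sigma: float) -> np.ndarray:
    raw = ndimage.gaussian_filter1d(rng.normal(size=n), sigma, mode="wrap")
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros(n)
    return raw / sd * amp


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    sd = raw.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return raw / sd


def _rng_for(spec: SceneSpec, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                int(spec.geometry_seed) & 0x7FFFFFFF]))


def _split_skin_geometry(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.output_size
    x = np.arange(w)
    center = h * 0.5 + _smooth_curve(rng, w, h * 0.05, w / 6)
    half = np.clip(h * 0.22 + _smooth_curve(rng, w, h * 0.03, w / 8), h * 0.10, h * 0.45)
    top, bottom = center - half, center + half
    split = np.clip(center + _smooth_curve(rng, w, h * 0.04, w / 10),
                    top + 6, bottom - 6)
    gap_raw = _smooth_curve(rng, w, 1.0, w / 8)
    thr = np.quantile(gap_raw, spec.attachment_fraction)
    gap_half = np.clip(gap_raw - thr, 0.0, None)
    mx = gap_half.max()
    if mx > 0:
        # where the split is open it opens clearly: the cleft has a floor
        # width, so roof and floor fluorescence stay visually separable
        gap_half = gap_half / mx * (h * 0.035)
        gap_half[gap_half > 0] += h * 0.025
    yy = np.arange(h)[:, None].astype(float)
    in_band = (yy >= top) & (yy <= bottom)
    roof = in_band & (yy <= split - gap_half) & (yy <= split)
    floor = in_band & (yy > split + gap_half)
    inter = in_band & ~roof & ~floor
    mask = np.zeros((h, w), dtype=np.int64)
    mask[roof] = SPLIT_SKIN_CLASSES["roof"]
    mask[floor] = SPLIT_SKIN_CLASSES["floor"]
    mask[inter] = SPLIT_SKIN_CLASSES["interspace"]
    return mask


def _esophagus_geometry(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.output_size
    # layer thickness fractions, top to bottom; BMZ gets a fixed thin height
    bmz_h = max(2, int(round(h * 0.006)))
    fracs = [("background", 0.10), ("epithelium", 0.22), ("bmz", None),
             ("lamina_propria", 0.12), ("muscular_mucosa", 0.10),
             ("circular_muscle", 0.16), ("longitudinal_muscle", 0.16)]
    mask = np.zeros((h, w), dtype=np.int64)
    yy = np.arange(h)[:, None].astype(float)
    cursor = np.zeros(w)
    for name, frac in fracs:
        if frac is None:
            thick = np.full(w, float(bmz_h))
        else:
            jitter = _smooth_curve(rng, w, h * 0.015, w / 7)
            thick = np.clip(h * frac + jitter, h * 0.02, None)
        nxt = cursor + thick
        if name != "background":
            band = (yy >= cursor) & (yy < nxt)
            mask[band] = ESOPHAGUS_CLASSES[name]
        cursor = nxt
    return mask  # rows below the last boundary stay background


def _attention_band(mask: np.ndarray, side: str) -> np.ndarray:
    """Pixels carrying a split-skin linear reaction: the dilation-overlap
    line of the given side, thickened by one disc step."""
    r = mask == SPLIT_SKIN_CLASSES["roof"]
    f = mask == SPLIT_SKIN_CLASSES["floor"]
    i = mask == SPLIT_SKIN_CLASSES["interspace"]
    if side == "epidermal":
        line = dilate_disc(r, 3) & (dilate_disc(f, 3) | dilate_disc(i, 3)) & (r | i)
        return dilate_disc(line, 5) & (r | i)
    line = dilate_disc(f, 3) & (dilate_disc(r, 3) | dilate_disc(i, 3)) & (f | i)
    return dilate_disc(line, 5) & (f | i)


def _voronoi_mesh(shape, rng: np.random.Generator, cell_px: float = 13.0,
                  ridge_px: float = 1.3) -> np.ndarray:
    """Cell-border mesh: ridges of the second-minus-first Voronoi distance."""
    h, w = shape
    n_sites = max(4, int(h * w / cell_px ** 2))
    sites = rng.uniform(0, [h, w], size=(n_sites, 2))
    step = 2  # evaluate on a coarse grid, then upsample; keeps KD queries cheap
    gy, gx = np.mgrid[0:h:step, 0:w:step]
    pts = np.column_stack([gy.ravel(), gx.ravel()])
    d, _ = cKDTree(sites).query(pts, k=2)
    ridge = (d[:, 1] - d[:, 0]) < ridge_px * 2
    coarse = ridge.reshape(gy.shape)
    return np.kron(coarse, np.ones((step, step), dtype=bool))[:h, :w]


def generate_image(spec: SceneSpec, seed: int) -> tuple[LabeledImage, GroundTruth]:
    """Render one scene; returns the image and its exact ground truth."""
    bright = spec.active_brightness()  # validates pattern/brightness combo
    rng = _rng_for(spec, seed)
    h, w = spec.output_size

    if spec.substrate == "split_skin":
        mask = _split_skin_geometry(spec, rng)
        base_table = _SSS_BASE
        classes = SPLIT_SKIN_CLASSES
    else:
        mask = _esophagus_geometry(spec, rng)
        base_table = _ESO_BASE
        classes = ESOPHAGUS_CLASSES

    img = np.zeros((h, w))
    for name, cid in classes.items():
        img[mask == cid] = base_table[name]

    # tissue texture, scaled by noise_sd (noise_sd=0 -> flat rendering)
    tex_amp = 2.0 * spec.noise_sd
    if tex_amp > 0:
        for name, cid in classes.items():
            if name == "background":
                continue
            region = mask == cid
            if region.any():
                tex = _smooth_field(rng, (h, w), _TEXTURE_SIGMA.get(name, (2.0, 2.0)))
                img[region] += tex_amp * tex[region]
    else:
        # keep the generator's random stream aligned across noise settings
        pass

    # specific reactions
    pattern_masks: dict[str, np.ndarray] = {}
    for pat, beta in bright.items():
        if spec.substrate == "split_skin":
            band = _attention_band(mask, pat)
        elif pat == "BMZ":
            band = mask == ESOPHAGUS_CLASSES["bmz"]
        else:  # intercellular
            mesh = _voronoi_mesh((h, w), rng)
            band = mesh & (mask == ESOPHAGUS_CLASSES["epithelium"])
        pattern_masks[pat] = band
        soft = ndimage.gaussian_filter(band.astype(float), 0.8)
        mx = soft.max()
        if mx > 0:
            img += _PATTERN_AMP * beta * soft / mx

    # confounders (always negative for the disease patterns)
    if spec.confounder == "nuclear_speckle":
        host = (mask == SPLIT_SKIN_CLASSES["roof"]) if spec.substrate == "split_skin" \
            else (mask == ESOPHAGUS_CLASSES["epithelium"])
        if host.any():
            k = max(1, int(host.sum() / 900))
            rows, cols = np.nonzero(host)
            pick = rng.choice(len(rows), size=min(k, len(rows)), replace=False)
            speck = np.zeros((h, w))
            speck[rows[pick], cols[pick]] = 1.0
            img += 0.35 * np.clip(ndimage.gaussian_filter(speck, 1.6)
                                  / max(ndimage.gaussian_filter(speck, 1.6).max(), 1e-9), 0, 1)
    elif spec.confounder == "diffuse_unspecific":
        glow = _smooth_field(rng, (h, w), w / 10)
        img[mask > 0] += 0.12 * np.clip(glow[mask > 0], 0, None)

    # shading + additive noise, both scaled by noise_sd
    if spec.noise_sd > 0:
        shading = 1.0 + 4.0 * spec.noise_sd * _smooth_field(rng, (h, w), w / 4)
        img *= np.clip(shading, 0.5, 1.5)
        img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    gt = GroundTruth(
        seg_mask=mask,
        pattern_labels=set(bright),
        brightness={p: brightness_to_score(b) for p, b in bright.items()},
        pattern_masks=pattern_masks,
        substrate=spec.substrate,
    )
    image = LabeledImage(pixels=img, substrate=spec.substrate)
    return image, gt


def dilution_brightness(titer_index: int, k: int) -> float:
    """Brightness beta at dilution step ``k`` for an endpoint at
    ``titer_index`` (the first negative step).

    For ``titer_index <= 5`` this is ``(titer_index - k) / 4``, so the score
    ``s = 1 + 4*beta`` drops by exactly one per dilution step — consistent
    with the additive titer rule ``d_{k+s-1}``.
    """
    if titer_index < 1:
        raise ValueError("titer_index must be >= 1")
    if k >= titer_index:
        return 0.0
    beta1 = min(1.0, (titer_index - 1) / 4.0)
    return beta1 * (titer_index - k) / (titer_index - 1)


def generate_dilution_series(base_spec: SceneSpec, titer_index: int,
                             n_dilutions: int, seed: int
                             ) -> list[tuple[LabeledImage, GroundTruth, int]]:
    """Render a serum's dilution series.

    Pattern brightness decreases strictly with the dilution index and is
    zero from ``titer_index`` on; each element depends only on
    ``(seed, dilution_index)``.
    """
    if titer_index < 1:
        raise ValueError("titer_index must be >= 1")
    if n_dilutions < 1:
        raise ValueError("n_dilutions must be >= 1")
    base_pattern = base_spec.pattern
    out = []
    for k in range(1, n_dilutions + 1):
        beta = dilution_brightness(titer_index, k)
        if beta > 0 and base_pattern != "none":
            spec_k = replace(base_spec, pattern=base_pattern, pattern_brightness=beta)
        else:
            spec_k = replace(base_spec, pattern="none", pattern_brightness=0.0)
        sub_seed = int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k])
                       .generate_state(1)[0] & 0x7FFFFFFF)
        img, gt = generate_image(spec_k, sub_seed)
        img.dilution_index = k
        out.append((img, gt, k))
    return out


@dataclass
class GenConfig:
    """Dataset-generation recipe: how many images of each pattern class."""

    substrate: str
    counts: dict[str, int]  # pattern (or 'none'/'both') -> count
    out_dir: Optional[str] = None
    output_size: tuple[int, int] = (1024, 1024)
    noise_sd: float = 0.02
    brightness_range: tuple[float, float] = (0.2, 1.0)
    confounder_rate: float = 0.2
    attachment_fraction: float = 0.3
    image_format: str = "tiff"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        d = dict(d)
        for key in ("output_size", "brightness_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def sample_scenes(config: GenConfig) -> list[tuple[SceneSpec, int]]:
    """Expand a config into reproducible per-image (spec, render seed) pairs."""
    master = np.random.default_rng(config.seed)
    scenes = []
    for pattern, count in sorted(config.counts.items()):
        for _ in range(int(count)):
            gseed = int(master.integers(0, 2 ** 31 - 1))
            rseed = int(master.integers(0, 2 ** 31 - 1))
            beta = float(master.uniform(*config.brightness_range))
            conf = "none"
            if master.random() < config.confounder_rate:
                conf = "nuclear_speckle" if master.random() < 0.5 else "diffuse_unspecific"
            spec = SceneSpec(
                substrate=config.substrate,
                pattern=pattern,
                pattern_brightness=beta if pattern != "none" else 0.0,
                confounder=conf,
                geometry_seed=gseed,
                noise_sd=config.noise_sd,
                output_size=config.output_size,
                attachment_fraction=config.attachment_fraction,
            )
            scenes.append((spec, rseed))
    return scenes


def render_scenes(config: GenConfig) -> list[tuple[SceneSpec, LabeledImage, GroundTruth]]:
    """Render every scene of a config in memory."""
    return [(spec, *generate_image(spec, rseed))
            for spec, rseed in sample_scenes(config)]


def generate_dataset(config: GenConfig | dict) -> pd.DataFrame:
    """Render a dataset to disk and return its manifest.

    Writes one grayscale image (TIFF or PNG) and one indexed-PNG mask per
    scene plus ``manifest.csv`` with columns (image_path, mask_path,
    substrate, pattern, brightness, dilution_index, serum_id, seed).
    """
    if isinstance(config, dict):
        config = GenConfig.from_dict(config)
    if config.out_dir is None:
        raise ValueError("config.out_dir is required to write a dataset")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if config.image_format in ("tif", "tiff") else ".png"
    rows = []
    for i, (spec, rseed) in enumerate(sample_scenes(config)):
        img, gt = generate_image(spec, rseed)
        img_path = out / f"img_{i:04d}{ext}"
        mask_path = out / f"mask_{i:04d}.png"
        save_gray(img_path, img.pixels, bits=16 if ext == ".tif" else 8)
        save_mask_png(mask_path, gt.seg_mask)
        score = max(gt.brightness.values(), default=np.nan)
        rows.append({
            "image_path": str(img_path), "mask_path": str(mask_path),
            "substrate": spec.substrate, "pattern": spec.pattern,
            "brightness": score, "dilution_index": "",
            "serum_id": f"s{i:04d}", "seed": rseed,
        })
    manifest = pd.DataFrame(rows, columns=[
        "image_path", "mask_path", "substrate", "pattern", "brightness",
        "dilution_index", "serum_id", "seed"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
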