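"""Image I/O, resampling and the binary-morphology primitives shared by both
tissue pipelines.

All rasters are 2-D ``float64`` arrays with intensities in ``[0, 1]``
(green-channel fluorescence). Binary masks are plain boolean arrays of the
same layout. Coordinates are ``(row, col)``, 0-based, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import imageio.v3 as iio
import tifffile
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "LabeledImage",
    "load_green",
    "save_gray",
    "save_mask_png",
    "load_mask_png",
    "resize_to",
    "resize_mask_to",
    "dilate_disc",
    "disc_footprint",
]


@dataclass
class LabeledImage:
    """A single-channel fluorescence raster plus optional acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D array, intensities normalized to ``[0, 1]``.
    source_size:
        ``(height, width)`` of the raster as loaded, before any resizing.
    serum_id, substrate, dilution_index:
        Optional serum-level metadata carried along the pipeline.
    """

    pixels: np.ndarray
    source_size: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    serum_id: Optional[str] = None
    substrate: Optional[str] = None
    dilution_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.source_size is None:
            self.source_size = self.pixels.shape
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0, 1]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def load_green(path: str | Path, **metadata) -> LabeledImage:
    """Load a TIFF/PNG image and return its green channel normalized to [0, 1].

    For RGB(A) input, channel index 1 is taken; single-channel input is used
    as-is. Integer rasters are divided by their dtype maximum, so a constant
    8-bit value 128 maps to 128/255.
    """
    arr = _read_array(path)
    if arr.ndim == 3:
        if arr.shape[-1] < 2:
            arr = arr[..., 0]
        else:
            arr = arr[..., 1]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        denom = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / denom
    elif np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported dtype {arr.dtype} in {path}")
    return LabeledImage(pixels=arr, source_size=arr.shape, **metadata)


def save_gray(path: str | Path, pixels: np.ndarray, bits: int = 16) -> None:
    """Write a [0, 1] raster as 8- or 16-bit grayscale TIFF/PNG."""
    path = Path(path)
    pixels = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    if bits == 8:
        arr = np.round(pixels * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write an integer label raster as single-channel 8-bit indexed PNG."""
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 255:
        raise ValueError("label values must fit in uint8")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(Path(path))


def load_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not single-channel")
    return arr.astype(np.int64)


def resize_to(image: LabeledImage | np.ndarray, target: tuple[int, int]) -> LabeledImage:
    """Bilinear resize of an intensity raster to ``target = (h, w)``.

    Non-square inputs are resampled anisotropically; the output intensity
    range stays within [0, 1].
    """
    th, tw = int(target[0]), int(target[1])
    if th < 8 or tw < 8:
        raise ValueError("target size must be at least 8x8")
    if isinstance(image, LabeledImage):
        pixels, meta = image.pixels, image
    else:
        pixels, meta = np.asarray(image, dtype=np.float64), None
    if pixels.shape == (th, tw):
        out = pixels.copy()
    else:
        out = _sk_resize(pixels, (th, tw), order=1, mode="reflect",
                         anti_aliasing=pixels.shape[0] > th or pixels.shape[1] > tw,
                         preserve_range=True)
        out = np.clip(out, 0.0, 1.0)
    return LabeledImage(
        pixels=out,
        source_size=meta.source_size if meta is not None else pixels.shape,
        serum_id=meta.serum_id if meta is not None else None,
        substrate=meta.substrate if meta is not None else None,
        dilution_index=meta.dilution_index if meta is not None else None,
    )


def resize_mask_to(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize for label/boolean rasters (label-preserving)."""
    mask = np.asarray(mask)
    th, tw = int(target[0]), int(target[1])
    if mask.shape == (th, tw):
        return mask.copy()
    out = _sk_resize(mask.astype(np.float64), (th, tw), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(mask.dtype)


def disc_footprint(diameter_px: int) -> np.ndarray:
    """Euclidean disc of the given odd pixel diameter, centred on the grid.

    The disc of diameter 3 has radius 1.5 and therefore contains the full
    3x3 neighbourhood (the corner offset distance sqrt(2) < 1.5).
    """
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ValueError("diameter must be an odd integer >= 1")
    r = diameter_px / 2.0
    k = (diameter_px - 1) // 2
    yy, xx = np.mgrid[-k:k + 1, -k:k + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2 + 1e-12


def dilate_disc(mask: np.ndarray, diameter_px: int = 3) -> np.ndarray:
    """Minkowski dilation of a boolean mask by a centred Euclidean disc."""
    mask = np.asarray(mask, dtype=bool)
    fp = disc_footprint(diameter_px)
    return ndimage.binary_dilation(mask, structure=fp)
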