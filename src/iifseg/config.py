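"""Run configuration: defaults, YAML loading and flag overrides."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    # working sizes (px); the classification raster is 4x the segmentation one
    "seg_size": 512,
    "cls_size": 2048,
    "dil_diameter": 3,  # structuring disc for the attention-line algebra
    # decision thresholds
    "threshold": 0.5,  # on the aggregated split-skin score y
    "eso_thresholds": {"BMZ": 0.5, "intercellular": 0.5},
    # intensity extraction
    "quantile": 0.95,
    "band_px": 20,  # desmosome band width at segmentation scale
    # patch sampling
    "n_patches": 40,
    "patch_size": 64,
    "seed": 0,
    "log_level": "INFO",
}


def load_config(path: Optional[str | Path] = None, **overrides) -> dict:
    """Merge defaults, an optional YAML file, and explicit overrides
    (later wins). Unknown keys are kept — configs may carry extra fields
    for the training commands."""
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg.update(loaded)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    if not 0.0 <= cfg["threshold"] <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return cfg
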