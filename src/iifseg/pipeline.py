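"""Serum-level composition of the two pipelines and the agreement report.

Each image yields a per-pattern call plus a brightness score; a serum's
dilution series is then folded into a titer with the capped series rule.
The evaluation report compares predicted calls/titers against a visual
reference reading: per-pattern confusion matrices, accuracy/PPA/NPA, and
the titer-deviation histogram.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eso import (ESO_PATTERNS, EsoModel, classify_eso, extract_bmz_mask,
                  pattern_region, region_intensity)
from .imaging import LabeledImage, resize_to
from .segmentation import SegModel, segment
from .sss import SIDE_PATTERN, PatchModel, classify_side
from .titer import (ConfusionMatrix, DilutionSeries, SeriesEntry,
                    confusion_metrics, titer_deviation, titer_series)

__all__ = [
    "predict_sss_image", "predict_eso_image", "predict_serum",
    "evaluate_agreement", "validate_result",
]


def _clamp_score(b: Optional[float]) -> Optional[float]:
    return None if b is None else float(np.clip(b, 1.0, 5.0))


def predict_sss_image(image: LabeledImage | np.ndarray, seg_model: SegModel,
                      roof_model: PatchModel, floor_model: PatchModel,
                      threshold: Optional[float] = None, seed: int = 0,
                      scale_factor: int = 4) -> dict:
    """Both-side split-skin result for one image (``threshold=None`` uses
    each side model's stored operating point)."""
    seg = segment(seg_model, image)
    sides = {}
    for side, model in (("roof", roof_model), ("floor", floor_model)):
        call, res = classify_side(image, seg, model, side, threshold=threshold,
                                  seed=seed, scale_factor=scale_factor)
        sides[side] = {
            "pattern": SIDE_PATTERN[side], "call": call,
            "y": res.y, "y_pos": res.y_pos, "y_neg": res.y_neg,
            "b": _clamp_score(res.b), "n_informative": res.n_informative,
        }
    return {"substrate": "split_skin", "sides": sides}


def predict_eso_image(image: LabeledImage | np.ndarray, seg_model: SegModel,
                      eso_model: EsoModel,
                      thresholds: Optional[dict[str, float]] = None,
                      quantile: float = 0.95, band_px: int = 20,
                      calibrations: Optional[dict] = None) -> dict:
    """Esophagus result for one image: calls, probabilities and, for each
    called pattern, the quantile intensity of its region.

    ``calibrations`` optionally maps pattern -> piecewise-linear knots
    ((raw, score), ...) for the intensity-to-score conversion; the default
    maps raw 0 -> 1 and raw 1 -> 5.
    """
    seg = segment(seg_model, image)
    size = (eso_model.cls_size, eso_model.cls_size)
    pixels = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    image_cls = resize_to(pixels, size).pixels
    bmz_cls = extract_bmz_mask(seg, out_size=size)
    cls = classify_eso(eso_model, image_cls, bmz_cls, thresholds=thresholds)
    work = resize_to(pixels, seg.working_size).pixels
    patterns = {}
    for pat in sorted(cls.calls):
        region = pattern_region(seg, pat, band_px=band_px)
        if region.any():
            knots = (calibrations or {}).get(pat, ((0.0, 1.0), (1.0, 5.0)))
            ri = region_intensity(work, region, q=quantile, calibration=knots)
            patterns[pat] = {"raw_intensity": ri.raw_intensity,
                             "score": _clamp_score(ri.score),
                             "region_px": int(region.sum())}
        else:
            patterns[pat] = {"raw_intensity": None, "score": None, "region_px": 0}
    return {"substrate": "esophagus",
            "calls": sorted(cls.calls), "negative": cls.negative,
            "probs": cls.probs, "patterns": patterns}


def _image_pattern_result(result: dict, pattern: str) -> tuple[str, Optional[float]]:
    """(call, score) for one pattern out of a per-image result dict."""
    if result["substrate"] == "split_skin":
        side = "roof" if pattern == "epidermal" else "floor"
        entry = result["sides"][side]
        return entry["call"], entry["b"]
    call = "positive" if pattern in result["calls"] else "negative"
    score = result["patterns"].get(pattern, {}).get("score")
    return call, score


def predict_serum(image_results: Sequence[tuple[dict, int]], serum_id: str,
                  patterns: Optional[Sequence[str]] = None) -> dict:
    """Fold per-image results (with their dilution indices) into a serum
    result with a titer per called pattern."""
    if not image_results:
        raise ValueError("no image results for serum")
    substrate = image_results[0][0]["substrate"]
    if patterns is None:
        patterns = tuple(SIDE_PATTERN.values()) if substrate == "split_skin" \
            else ESO_PATTERNS
    out = {"serum_id": serum_id, "substrate": substrate, "patterns": {}}
    for pattern in patterns:
        entries = []
        for result, k in sorted(image_results, key=lambda t: t[1]):
            call, score = _image_pattern_result(result, pattern)
            entries.append(SeriesEntry(k=k, call=call,
                                       score=score if call == "positive" else None))
        t = titer_series(DilutionSeries(serum_id=serum_id, pattern=pattern,
                                        entries=entries))
        out["patterns"][pattern] = {
            "call": "positive" if t.positive else "negative",
            "titer": t.denominator, "basis": t.basis,
        }
    return out


def evaluate_agreement(pred: pd.DataFrame, ref: pd.DataFrame) -> dict:
    """Agreement report between predicted and reference serum readings.

    Both frames need columns (serum_id, pattern, call, titer); titer may be
    empty/NaN for negatives. Returns per-pattern and combined confusion
    matrices with accuracy/PPA/NPA (percent) and the titer-deviation
    histogram over sera where both readings called the same pattern.
    """
    merged = pred.merge(ref, on=["serum_id", "pattern"], suffixes=("_pred", "_ref"))
    report: dict = {"patterns": {}, "skipped": []}
    patterns = sorted(merged["pattern"].unique())

    def _metrics(df: pd.DataFrame) -> dict:
        p = df["call_pred"] == "positive"
        r = df["call_ref"] == "positive"
        cm = ConfusionMatrix(tp=int((p & r).sum()), fp=int((p & ~r).sum()),
                             fn=int((~p & r).sum()), tn=int((~p & ~r).sum()))
        entry = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        try:
            acc, ppa, npa = confusion_metrics(cm)
            entry.update(accuracy=round(acc, 1), ppa=round(ppa, 1),
                         npa=round(npa, 1))
        except ZeroDivisionError as exc:
            entry["undefined"] = str(exc)
        return entry

    for pattern in patterns:
        report["patterns"][pattern] = _metrics(merged[merged["pattern"] == pattern])

    # combined: serum positive if any pattern positive
    def _combine(df, call_col):
        return df.groupby("serum_id")[call_col].apply(
            lambda s: "positive" if (s == "positive").any() else "negative")

    comb = pd.DataFrame({"call_pred": _combine(merged, "call_pred"),
                         "call_ref": _combine(merged, "call_ref")})
    report["combined"] = _metrics(comb)

    both = merged[(merged["call_pred"] == "positive")
                  & (merged["call_ref"] == "positive")]
    pred_t = {(row.serum_id, row.pattern): int(row.titer_pred)
              for row in both.itertuples()
              if pd.notna(row.titer_pred)}
    ref_t = {(row.serum_id, row.pattern): int(row.titer_ref)
             for row in both.itertuples()
             if pd.notna(row.titer_ref)}
    log: list = []
    hist = titer_deviation(pred_t, ref_t, log=log)
    report["titer_deviation"] = {str(k): v for k, v in sorted(hist.items())}
    report["skipped"] = log
    return report


# -- minimal structural validation of result JSON (schema shipped alongside) --

_SIDE_KEYS = {"pattern", "call", "y", "y_pos", "y_neg", "b", "n_informative"}


def validate_result(result: dict) -> None:
    """Check a per-image result dict against the shipped result schema."""
    substrate = result.get("substrate")
    if substrate == "split_skin":
        sides = result.get("sides")
        if not isinstance(sides, dict) or set(sides) != {"roof", "floor"}:
            raise ValueError("split-skin result needs 'roof' and 'floor' sides")
        for side, entry in sides.items():
            missing = _SIDE_KEYS - set(entry)
            if missing:
                raise ValueError(f"side {side} missing keys {sorted(missing)}")
            if entry["call"] not in ("positive", "negative"):
                raise ValueError("call must be positive or negative")
            if not 0.0 <= entry["y"] <= 1.0:
                raise ValueError("y outside [0,1]")
    elif substrate == "esophagus":
        for key in ("calls", "negative", "probs", "patterns"):
            if key not in result:
                raise ValueError(f"esophagus result missing {key!r}")
        if bool(result["calls"]) == bool(result["negative"]):
            raise ValueError("'negative' must mirror an empty call set")
        for p, v in result["probs"].items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability for {p} outside [0,1]")
    else:
        raise ValueError(f"unknown substrate {substrate!r}")
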