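"""Dilution-series titer estimation and agreement statistics.

Dilutions follow the canonical half-log series 1:10, 1:32, 1:100, 1:320,
1:1000, ... (alternating x3.2 / x3.125 steps). For a single image at
dilution index ``k`` with brightness score ``s`` in [1, 5], the titer is
``d_{k + s - 1}`` — each score step corresponds to one further dilution
step. Across a series, the lowest dilution read negative caps the result:
the titer is computed from the highest-dilution positive image below it and
clamped to stay below the negative dilution; with no negative image the
highest-dilution image is used directly.

Agreement with a visual reference reading is summarized by accuracy,
positive percent agreement (PPA = sensitivity) and negative percent
agreement (NPA = specificity) from 2x2 confusion matrices, and by the
histogram of titer deviations in dilution steps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "dilution_denominator", "dilution_index", "titer_single", "titer_series",
    "TiterResult", "SeriesEntry", "DilutionSeries", "ConfusionMatrix",
    "confusion_metrics", "titer_deviation",
]

_BASE_SERIES = (10, 32, 100, 320, 1000, 3200, 10000)


def dilution_denominator(k: int) -> int:
    """k-th member (1-based) of the canonical series, extended by the
    alternating half-log pattern beyond the printed terms."""
    if k < 1:
        raise ValueError("dilution index must be >= 1")
    if k <= len(_BASE_SERIES):
        return _BASE_SERIES[k - 1]
    decades, rem = divmod(k - 1, 2)
    return int(10 ** (decades + 1) * (3.2 if rem else 1))


def dilution_index(denominator: int) -> int:
    """Inverse of :func:`dilution_denominator` for members of the series."""
    k = 1
    while dilution_denominator(k) < denominator:
        k += 1
        if k > 64:
            raise ValueError(f"{denominator} is not on the canonical series")
    if dilution_denominator(k) != denominator:
        raise ValueError(f"{denominator} is not on the canonical series")
    return k


@dataclass
class TiterResult:
    pattern: str
    denominator: Optional[int]  # None for a negative serum
    basis: str  # single_image | capped_by_negative | open_ended | negative

    @property
    def positive(self) -> bool:
        return self.denominator is not None


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def titer_single(k: int, s: float, pattern: str = "") -> TiterResult:
    """Single-image titer: ``d_{k + s - 1}`` with the score rounded to the
    nearest integer (ties round up)."""
    if k < 1:
        raise ValueError("dilution index k must be >= 1")
    if not 1.0 <= s <= 5.0:
        raise ValueError(f"brightness score must lie in [1, 5], got {s}")
    idx = k + _round_half_up(s) - 1
    return TiterResult(pattern=pattern, denominator=dilution_denominator(idx),
                       basis="single_image")


@dataclass
class SeriesEntry:
    k: int  # dilution index on the canonical series
    call: str  # 'positive' | 'negative'
    score: Optional[float] = None  # required when positive


@dataclass
class DilutionSeries:
    serum_id: str
    pattern: str
    entries: list[SeriesEntry]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("a dilution series needs at least one entry")
        ks = [e.k for e in self.entries]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("dilution indices must be strictly increasing")


def titer_series(series: DilutionSeries) -> TiterResult:
    """Serum-level titer for one pattern across a dilution series.

    The lowest-dilution negative entry (index ``m``) defines a cap: the
    titer is computed from the highest-dilution positive entry below ``m``
    and clamped to ``d_{m-1}`` at most. With no negative entry the
    highest-dilution entry is used uncapped; an all-negative series yields
    a negative result without a titer.
    """
    pattern = series.pattern
    negatives = [e.k for e in series.entries if e.call == "negative"]
    positives = [e for e in series.entries if e.call == "positive"]
    if not positives:
        return TiterResult(pattern=pattern, denominator=None, basis="negative")
    if negatives:
        m = min(negatives)
        below = [e for e in positives if e.k < m]
        if not below:
            return TiterResult(pattern=pattern, denominator=None, basis="negative")
        e = max(below, key=lambda e: e.k)
        if e.score is None:
            raise ValueError("positive series entries need a brightness score")
        raw = titer_single(e.k, e.score, pattern)
        capped = min(dilution_index(raw.denominator), m - 1)
        return TiterResult(pattern=pattern,
                           denominator=dilution_denominator(capped),
                           basis="capped_by_negative")
    e = max(positives, key=lambda e: e.k)
    if e.score is None:
        raise ValueError("positive series entries need a brightness score")
    raw = titer_single(e.k, e.score, pattern)
    basis = "single_image" if len(series.entries) == 1 else "open_ended"
    return TiterResult(pattern=pattern, denominator=raw.denominator, basis=basis)


@dataclass
class ConfusionMatrix:
    """2x2 agreement counts against the visual reference reading."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, PPA, NPA) in percent.

    accuracy = 100 (tp+tn)/total, PPA = 100 tp/(tp+fn), NPA = 100 tn/(tn+fp).
    A zero denominator makes the corresponding quantity undefined and is
    signalled rather than returned as NaN.
    """
    if cm.total == 0:
        raise ZeroDivisionError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("no reference positives: PPA undefined")
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("no reference negatives: NPA undefined")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    ppa = 100.0 * cm.tp / (cm.tp + cm.fn)
    npa = 100.0 * cm.tn / (cm.tn + cm.fp)
    return accuracy, ppa, npa


def titer_deviation(pred_titers: dict, ref_titers: dict,
                    log: Optional[list] = None) -> Counter:
    """Histogram of titer deviations in dilution steps.

    Keys of both dicts are (serum_id, pattern); values are titer
    denominators on the canonical series. Only pairs present and positive
    in both readings are compared (pattern must agree); unmatched keys are
    skipped and, when ``log`` is given, recorded there. Negative deviation
    means the prediction underestimates the reference.
    """
    hist: Counter = Counter()
    for key, pred in pred_titers.items():
        if key not in ref_titers:
            if log is not None:
                log.append(f"unmatched prediction {key}: skipped")
            continue
        ref = ref_titers[key]
        if pred is None or ref is None:
            if log is not None:
                log.append(f"non-positive pair {key}: skipped")
            continue
        hist[dilution_index(pred) - dilution_index(ref)] += 1
    if log is not None:
        for key in ref_titers:
            if key not in pred_titers:
                log.append(f"unmatched reference {key}: skipped")
    return hist


# printed validation counts of the reference study, kept as module data so
# the evaluation arithmetic can be exercised without the non-public images
TABLE_SPLIT_SKIN = {
    "combined": ConfusionMatrix(tp=31, fp=4, fn=1, tn=73),
    "epidermal": ConfusionMatrix(tp=25, fp=3, fn=1, tn=80),
    "dermal": ConfusionMatrix(tp=8, fp=3, fn=0, tn=98),
}
TABLE_ESOPHAGUS = {
    "combined": ConfusionMatrix(tp=46, fp=0, fn=3, tn=61),
    "BMZ": ConfusionMatrix(tp=27, fp=2, fn=3, tn=78),
    "intercellular": ConfusionMatrix(tp=20, fp=0, fn=0, tn=90),
}
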