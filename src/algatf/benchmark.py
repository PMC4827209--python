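"""Accuracy evaluation against a gold standard.

Per family: TP (predicted and gold), FP (predicted, not gold), FN (gold,
not predicted), sensitivity = TP/(TP+FN) and positive predictive value
PPV = TP/(TP+FP). Undefined ratios (zero denominator) are reported as NA,
never coerced to 0 or 1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .records import Assignment, GoldStandard


@dataclass(frozen=True)
class FamilyMetrics:
    family: str
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> Optional[float]:
        return sensitivity(self.tp, self.fn)

    @property
    def ppv(self) -> Optional[float]:
        return ppv(self.tp, self.fp)


def sensitivity(tp: int, fn: int) -> Optional[float]:
    """TP / (TP + FN); None when there are no gold members."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def ppv(tp: int, fp: int) -> Optional[float]:
    """TP / (TP + FP); None when nothing was predicted."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def _predicted_labels(predicted: Iterable[Assignment] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(predicted, Mapping):
        return dict(predicted)
    return {a.protein_id: a.label for a in predicted if a.is_classified}


def confusion_counts(
    predicted: Iterable[Assignment] | Mapping[str, str],
    gold: GoldStandard,
    family: str,
) -> tuple[int, int, int]:
    """(tp, fp, fn) for one family."""
    pred = _predicted_labels(predicted)
    pred_ids = {p for p, f in pred.items() if f == family}
    gold_ids = gold.members(family)
    tp = len(pred_ids & gold_ids)
    fp = len(pred_ids - gold_ids)
    fn = len(gold_ids - pred_ids)
    return tp, fp, fn


def benchmark_report(
    predicted: Iterable[Assignment] | Mapping[str, str],
    gold: GoldStandard,
    families: Sequence[str],
) -> list[FamilyMetrics]:
    """One FamilyMetrics per requested family."""
    pred = _predicted_labels(predicted)
    return [FamilyMetrics(f, *confusion_counts(pred, gold, f)) for f in families]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (proportion display)."""
    factor = 10**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def truncate(x: float, decimals: int = 2) -> float:
    """Decimal truncation toward zero.

    Ratio displays truncate rather than round: a sensitivity or PPV below
    one never prints as 1 (e.g. 224/225 prints as 0.99), so a printed 1
    always means a perfect score.
    """
    factor = 10**decimals
    return math.trunc(x * factor) / factor


def format_ratio(value: Optional[float], decimals: int = 2) -> str:
    if value is None:
        return "NA"
    return f"{truncate(value, decimals):.{decimals}f}".rstrip("0").rstrip(".") or "0"


def write_report(path: str | os.PathLike, metrics: Sequence[FamilyMetrics]) -> None:
    """TSV rendering: family, tp/gold and tp/predicted fractions, ratios."""
    with open(path, "w") as fh:
        fh.write(
            "family\ttp\tfp\tfn\tsensitivity_fraction\tppv_fraction"
            "\tsensitivity\tppv\n"
        )
        for m in metrics:
            sens_frac = f"{m.tp}/{m.tp + m.fn}"
            ppv_frac = f"{m.tp}/{m.tp + m.fp}"
            fh.write(
                f"{m.family}\t{m.tp}\t{m.fp}\t{m.fn}\t{sens_frac}\t{ppv_frac}"
                f"\t{format_ratio(m.sensitivity)}\t{format_ratio(m.ppv)}\n"
            )
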