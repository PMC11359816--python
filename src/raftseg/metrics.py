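"""Pixel-level evaluation: confusion counts and the derived metric suite.

Metrics are micro-averaged: confusion counts are pooled over the whole
evaluation set before any ratio is formed, matching how single
dataset-level scores are conventionally reported for segmentation.

Degenerate denominators follow explicit conventions: a ratio whose
denominator is zero is reported as 0 and flagged; when expected
agreement EA reaches 1 the kappa coefficient is reported as 0 and
flagged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts", "compute_metrics"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    iou: float
    oa: float
    ea: float
    kappa: float
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall, "f1": self.f1,
                "iou": self.iou, "oa": self.oa, "ea": self.ea, "kappa": self.kappa}

    def to_text(self) -> str:
        lines = [f"{k}\t{v:.6f}" for k, v in self.as_dict().items()]
        if self.flags:
            lines.append("flags\t" + ",".join(self.flags))
        return "\n".join(lines) + "\n"

    def append_csv(self, path, extra: dict | None = None) -> None:
        path = Path(path)
        row = dict(extra or {})
        row.update(self.as_dict())
        row["flags"] = ";".join(self.flags)
        write_header = not path.exists()
        with open(path, "a", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(row))
            if write_header:
                writer.writeheader()
            writer.writerow(row)


def confusion_counts(pred_mask, true_mask) -> ConfusionCounts:
    """Exact TP/FP/FN/TN pixel tallies for two binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    for name, a in (("prediction", p), ("truth", t)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """Precision, recall, F1, IoU, overall accuracy, expected agreement
    and kappa from pooled confusion counts."""
    tp, fp, fn, tn = cc.tp, cc.fp, cc.fn, cc.tn
    total = cc.total
    if total <= 0:
        raise ValueError("confusion counts are empty")
    flags: list = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1")
    iou = ratio(tp, tp + fp + fn, "iou")
    oa = (tp + tn) / total
    ea = ((tp + fn) * (tp + fp) + (tn + fn) * (tn + fp)) / (total * total)
    if ea >= 1.0:
        flags.append("kappa_undefined")
        kappa = 0.0
    else:
        kappa = (oa - ea) / (1.0 - ea)
    return MetricsReport(precision, recall, f1, iou, oa, ea, kappa, flags)
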