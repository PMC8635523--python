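"""Per-class precision/recall/F1 reports with macro and weighted averages."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .respsynth import VOCABULARY


@dataclass
class ClassificationReport:
    """Evaluation summary: per-class precision, recall, F1 and supports,
    plus accuracy and macro/weighted averages.  Metrics with vanishing
    denominators are reported as 0."""

    vocabulary: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    zero_support_classes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "zero_support_classes": list(self.zero_support_classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationReport":
        return cls(
            vocabulary=tuple(d["vocabulary"]),
            precision=d["precision"], recall=d["recall"], f1=d["f1"],
            support=d["support"], accuracy=d["accuracy"],
            macro_avg=d["macro_avg"], weighted_avg=d["weighted_avg"],
            zero_support_classes=tuple(d["zero_support_classes"]),
        )


def compute_report(true_labels: Sequence[str], predicted_labels: Sequence[str],
                   vocabulary: Sequence[str] = VOCABULARY) -> ClassificationReport:
    """Compute the full report from paired label sequences.

    precision_c = TP/(TP+FP), recall_c = TP/(TP+FN), F1 their harmonic mean
    (all 0 when undefined); macro averages are unweighted means over
    classes, weighted averages are support-weighted.  The support-weighted
    recall always equals the overall accuracy.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    if len(true_labels) == 0:
        raise ValueError("need at least one labelled example")
    for token in list(true_labels) + list(predicted_labels):
        if token not in vocabulary:
            raise ValueError(f"unknown class token {token!r}")
    vocabulary = tuple(vocabulary)
    prec, rec, f1, support = precision_recall_fscore_support(
        true_labels, predicted_labels, labels=list(vocabulary), zero_division=0
    )
    accuracy = float(np.mean(np.asarray(true_labels) == np.asarray(predicted_labels)))
    total = int(support.sum())
    weighted = {
        "precision": float(np.sum(prec * support) / total),
        "recall": float(np.sum(rec * support) / total),
        "f1": float(np.sum(f1 * support) / total),
    }
    macro = {
        "precision": float(np.mean(prec)),
        "recall": float(np.mean(rec)),
        "f1": float(np.mean(f1)),
    }
    return ClassificationReport(
        vocabulary=vocabulary,
        precision={c: float(p) for c, p in zip(vocabulary, prec)},
        recall={c: float(r) for c, r in zip(vocabulary, rec)},
        f1={c: float(v) for c, v in zip(vocabulary, f1)},
        support={c: int(s) for c, s in zip(vocabulary, support)},
        accuracy=accuracy,
        macro_avg=macro,
        weighted_avg=weighted,
        zero_support_classes=tuple(c for c, s in zip(vocabulary, support) if s == 0),
    )


def _round2(x: float) -> float:
    """Round-half-up to two decimals (display convention of the tables)."""
    return math.floor(x * 100 + 0.5) / 100


def format_report(report: ClassificationReport) -> str:
    """Table layout: class rows, then Accuracy, Macro avg, Weighted avg."""
    width = max(len(c) for c in report.vocabulary) + 2
    lines = [f"{'':<{width}}Precision  Recall  F1-score  Support"]
    for c in sorted(report.vocabulary):
        lines.append(
            f"{c:<{width}}{_round2(report.precision[c]):>9.2f}"
            f"{_round2(report.recall[c]):>8.2f}"
            f"{_round2(report.f1[c]):>10.2f}{report.support[c]:>9d}"
        )
    lines.append(f"{'Accuracy':<{width}}{'':>9}{'':>8}"
                 f"{_round2(report.accuracy):>10.2f}")
    for name, avg in (("Macro avg", report.macro_avg),
                      ("Weighted avg", report.weighted_avg)):
        lines.append(
            f"{name:<{width}}{_round2(avg['precision']):>9.2f}"
            f"{_round2(avg['recall']):>8.2f}{_round2(avg['f1']):>10.2f}"
        )
    return "\n".join(lines) + "\n"


def export_report(report: ClassificationReport, path: str | Path,
                  format: str = "text") -> Path:
    """Write the report as ``text`` (table layout, 2 decimals), ``json``
    (full precision, round-trippable) or ``csv``."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2))
    elif format == "csv":
        lines = ["class,precision,recall,f1,support"]
        for c in report.vocabulary:
            lines.append(f"{c},{report.precision[c]!r},{report.recall[c]!r},"
                         f"{report.f1[c]!r},{report.support[c]}")
        lines.append(f"accuracy,{report.accuracy!r},,,")
        lines.append(f"macro_avg,{report.macro_avg['precision']!r},"
                     f"{report.macro_avg['recall']!r},{report.macro_avg['f1']!r},")
        lines.append(f"weighted_avg,{report.weighted_avg['precision']!r},"
                     f"{report.weighted_avg['recall']!r},"
                     f"{report.weighted_avg['f1']!r},")
        path.write_text("\n".join(lines) + "\n")
    elif format == "text":
        path.write_text(format_report(report))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
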