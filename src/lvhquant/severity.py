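"""Four-band severity scoring of regional wall thickness and the
classification metrics used to evaluate it.

Scores follow the clinical grading used throughout the package:

* 0, normal: RWT < 15 mm
* 1, mild: 15 mm <= RWT <= 20 mm
* 2, moderate: 20 mm < RWT <= 25 mm
* 3, severe: RWT > 25 mm

The band edges are deliberately closed/open exactly as written; 20.0 mm is
mild and 25.0 mm is moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from lvhquant.aha import RegionPartition
    from lvhquant.thickness import ThicknessReport

CLASS_NAMES = ("normal", "mild", "moderate", "severe")


def score_severity(rwt_mm):
    """Severity score 0-3 for a wall thickness in millimetres.

    Accepts a scalar or array; rejects negative thickness.
    """
    arr = np.asarray(rwt_mm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("wall thickness must be non-negative")
    score = np.zeros(arr.shape, dtype=int)
    score[arr >= 15.0] = 1
    score[arr > 20.0] = 2
    score[arr > 25.0] = 3
    if np.isscalar(rwt_mm) or arr.ndim == 0:
        return int(score)
    return score


@dataclass
class SeverityMap:
    """Per-region severity scores under a given partition mode."""

    scores: dict[int, int]
    mode: int = 49
    class_names: tuple[str, ...] = CLASS_NAMES

    def class_name(self, region_id: int) -> str:
        return self.class_names[self.scores[region_id]]

    def counts(self) -> list[int]:
        vals = list(self.scores.values())
        return [vals.count(c) for c in range(len(self.class_names))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"region_id": rid, "score": s, "class_name": self.class_names[s]}
                for rid, s in sorted(self.scores.items())
            ]
        )

    def to_csv(self, path: str) -> str:
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str, mode: int = 49) -> "SeverityMap":
        import pandas as pd

        df = pd.read_csv(path)
        return cls({int(r.region_id): int(r.score) for r in df.itertuples()}, mode=mode)


def score_report(report: "ThicknessReport", partition: "RegionPartition | None" = None) -> SeverityMap:
    """Score every region of a thickness report; missing regions reject."""
    scores = {rid: int(score_severity(v)) for rid, v in report.mean_rwt.items()}
    mode = 49
    if partition is not None:
        mode = partition.mode
        missing = set(partition.region_ids) - set(scores)
        if missing:
            raise ValueError(f"thickness report is missing regions {sorted(missing)}")
    return SeverityMap(scores=scores, mode=mode)


@dataclass(frozen=True)
class ConfusionMetrics:
    accuracy: float  # percent
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # a zero-denominator metric was reported as 0


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Accuracy (%), precision, recall and F1 from confusion counts.

    Undefined precision/recall (zero denominator) is reported as 0 with the
    ``degenerate`` flag set, which keeps degenerate splits comparable.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts must not all be zero")
    accuracy = (tp + tn) / total * 100.0
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ConfusionMetrics(accuracy, precision, recall, f1, degenerate)


@dataclass
class EvalReport:
    """Macro-averaged one-vs-rest classification metrics, 4 classes."""

    accuracy: float  # overall percent correct
    macro_accuracy: float  # unweighted mean of per-class one-vs-rest accuracies
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: list[ConfusionMetrics] = field(default_factory=list)
    confusion_counts: list[tuple[int, int, int, int]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for c, (m, counts) in enumerate(zip(self.per_class, self.confusion_counts)):
            rows.append(
                {
                    "class": CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c),
                    "tp": counts[0],
                    "tn": counts[1],
                    "fp": counts[2],
                    "fn": counts[3],
                    "accuracy_pct": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
        return pd.DataFrame(rows)


def macro_metrics(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 4) -> EvalReport:
    """One-vs-rest confusion counts per class, macro-averaged metrics.

    Macro averaging computes each metric independently per class and takes
    the unweighted mean, so rare severity grades weigh as much as common
    ones.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise ValueError("empty input")
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if yt.min() < 0 or yt.max() >= n_classes or yp.min() < 0 or yp.max() >= n_classes:
        raise ValueError("labels out of range")
    per_class: list[ConfusionMetrics] = []
    counts: list[tuple[int, int, int, int]] = []
    for c in range(n_classes):
        tp = int(np.sum((yt == c) & (yp == c)))
        tn = int(np.sum((yt != c) & (yp != c)))
        fp = int(np.sum((yt != c) & (yp == c)))
        fn = int(np.sum((yt == c) & (yp != c)))
        counts.append((tp, tn, fp, fn))
        per_class.append(confusion_metrics(tp, tn, fp, fn))
    return EvalReport(
        accuracy=float(np.mean(yt == yp) * 100.0),
        macro_accuracy=float(np.mean([m.accuracy for m in per_class])),
        macro_precision=float(np.mean([m.precision for m in per_class])),
        macro_recall=float(np.mean([m.recall for m in per_class])),
        macro_f1=float(np.mean([m.f1 for m in per_class])),
        per_class=per_class,
        confusion_counts=counts,
    )
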