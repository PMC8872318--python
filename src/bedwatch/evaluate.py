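"""Event-level evaluation: matching, confusion matrices and metrics.

A detected bed-exit matches a true one when their start times agree
within a tolerance (default 10 s), matched greedily one-to-one in time
order.  Negative instances are true non-exit episodes (sit-up, roll-over,
edge-sit returns, pass-throughs, left items): an episode with no detected
exit inside it counts as a true negative.  Metrics are the standard
event-level accuracy, precision, sensitivity and specificity, reported as
percentages rounded half-up to one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .geometry import InputError
from .posture import EventRecord, EventType

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 10.0  # s


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricSet:
    """Percentages in [0, 100]; None where the ratio is undefined (0/0)."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None

    def rounded(self, digits: int = 1) -> "MetricSet":
        return MetricSet(
            *(
                round_half_up(v, digits) if v is not None else None
                for v in (self.accuracy, self.precision, self.sensitivity, self.specificity)
            )
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def round_half_up(value: float, digits: int = 1) -> float:
    """Round with ties away from zero (table presentation convention)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def metrics_from_counts(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy / precision / sensitivity / specificity as percentages.

    Ratios with a zero denominator are reported as None (absent), never
    silently as 0.
    """
    if cm.total == 0:
        raise InputError("empty confusion matrix")

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            logger.warning("%s undefined: zero denominator", name)
            return None
        return 100.0 * num / den

    return MetricSet(
        accuracy=ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        precision=ratio(cm.tp, cm.tp + cm.fp, "precision"),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=ratio(cm.tn, cm.tn + cm.fp, "specificity"),
    )


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------


def _starts(events, event_type: str | None = "BED_EXIT") -> list[float]:
    out = []
    for e in events:
        if isinstance(e, EventRecord):
            if event_type and e.event_type != EventType.BED_EXIT:
                continue
            out.append(e.start)
        elif isinstance(e, dict):
            if event_type and e.get("event_type", "BED_EXIT") != event_type:
                continue
            out.append(float(e["start"]))
        else:
            out.append(float(e))
    return out


def match_events(
    detected,
    truth,
    tolerance: float = DEFAULT_TOLERANCE,
    negatives: list[tuple[float, float]] | None = None,
) -> ConfusionMatrix:
    """Match detected bed-exits to truth and count the confusion matrix.

    ``detected`` and ``truth`` may be :class:`EventRecord` lists, dicts
    with ``start`` keys, or bare start times.  Matching is greedy and
    one-to-one in time order; a pair matches when start times differ by at
    most ``tolerance`` seconds.  ``negatives`` are true non-exit episodes
    ``(start, end)``; an episode with no detected exit starting inside it
    is a TN, one containing a (necessarily unmatched) detection is not.
    """
    det = sorted(_starts(detected))
    tru = sorted(_starts(truth))
    negatives = negatives or []
    _check_no_overlap(tru, negatives)

    matched_det: set[int] = set()
    matched_tru: set[int] = set()
    ti = 0
    for di, d in enumerate(det):
        # earliest unmatched truth within tolerance (time-ordered greedy)
        while ti < len(tru) and tru[ti] < d - tolerance:
            ti += 1
        for tj in range(ti, len(tru)):
            if tru[tj] > d + tolerance:
                break
            if tj not in matched_tru:
                matched_tru.add(tj)
                matched_det.add(di)
                break

    tp = len(matched_det)
    fp = len(det) - tp
    fn = len(tru) - tp
    unmatched = [d for i, d in enumerate(det) if i not in matched_det]
    tn = 0
    for start, end in negatives:
        if not any(start <= d < end for d in unmatched):
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _check_no_overlap(truth_starts: list[float], negatives) -> None:
    intervals = sorted((float(s), float(e)) for s, e, *_ in negatives)
    for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise InputError("overlapping truth episodes")


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def report(per_category: dict[str, ConfusionMatrix]) -> tuple[str, pd.DataFrame]:
    """Render confusion matrices + metrics per category (and overall).

    Returns (markdown text, tidy DataFrame).  Categories are typically
    ``non_assisted`` and ``assisted``; an ``overall`` row is added when
    more than one category is present.
    """
    cats = dict(per_category)
    if len(cats) > 1 and "overall" not in cats:
        total = ConfusionMatrix()
        for cm in cats.values():
            total = total + cm
        cats["overall"] = total

    rows = []
    for name, cm in cats.items():
        row = {"category": name, "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn}
        if cm.total > 0:
            m = metrics_from_counts(cm).rounded()
            row.update(
                accuracy_pct=m.accuracy,
                precision_pct=m.precision,
                sensitivity_pct=m.sensitivity,
                specificity_pct=m.specificity,
            )
        else:
            row.update(
                accuracy_pct=None, precision_pct=None, sensitivity_pct=None, specificity_pct=None
            )
        rows.append(row)
    df = pd.DataFrame(rows)

    def fmt(v):
        return "-" if v is None or pd.isna(v) else f"{v:g}%"

    lines = [
        "| Category | TP | TN | FP | FN | Accuracy | Precision | Sensitivity | Specificity |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            f"| {r['category']} | {r['tp']} | {r['tn']} | {r['fp']} | {r['fn']} | "
            f"{fmt(r['accuracy_pct'])} | {fmt(r['precision_pct'])} | "
            f"{fmt(r['sensitivity_pct'])} | {fmt(r['specificity_pct'])} |"
        )
    return "\n".join(lines) + "\n", df
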