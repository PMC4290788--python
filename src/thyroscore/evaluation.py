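"""One-vs-rest evaluation with per-subtype and micro-averaged P/R/F1.

Predicted label sets are scored against a gold standard of subtype
labels.  Each subtype is evaluated separately (multi-label documents
contribute to several subtypes); ``TC``/``NON`` predictions count as
negative for every subtype.  The evaluation universe is the set of
gold pmids: predictions for documents outside the gold standard are
ignored, and gold documents without a prediction count as all-negative.

Metrics follow the standard definitions ``P = TP/(TP+FP)``,
``R = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``, with any 0/0 defined as 0.
Micro-averaging pools the counts over subtypes before computing the
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .lexicon import SUBTYPES

Labels = Mapping[str, frozenset[str]]


@dataclass(frozen=True)
class SubtypeMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class EvaluationReport:
    """Per-subtype and micro-averaged confusion counts and metrics."""

    per_subtype: Mapping[str, SubtypeMetrics]
    micro: SubtypeMetrics

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subtype": j, "TP": m.tp, "TN": m.tn, "FN": m.fn, "FP": m.fp,
             "Precision": round(m.precision, 3), "Recall": round(m.recall, 3),
             "F1": round(m.f1, 3)}
            for j, m in self.per_subtype.items()
        ]
        m = self.micro
        rows.append({"subtype": "Micro Average", "TP": m.tp, "TN": m.tn,
                     "FN": m.fn, "FP": m.fp,
                     "Precision": round(m.precision, 3),
                     "Recall": round(m.recall, 3), "F1": round(m.f1, 3)})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def confusion_counts(predicted: Labels, gold: Labels,
                     subtype: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for one subtype over the gold pmids."""
    if subtype not in SUBTYPES:
        raise ValidationError(f"unknown subtype code {subtype!r}")
    tp = fp = fn = tn = 0
    for pmid, gold_labels in gold.items():
        gold_pos = subtype in gold_labels
        pred_pos = subtype in predicted.get(pmid, frozenset())
        if gold_pos and pred_pos:
            tp += 1
        elif gold_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts (0/0 -> 0)."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("confusion counts must be >= 0")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def micro_average(
    per_subtype_counts: Mapping[str, tuple[int, int, int, int]],
) -> tuple[float, float, float]:
    """Pool counts over subtypes, then compute P/R/F1."""
    if not per_subtype_counts:
        raise ValidationError("micro_average needs at least one subtype")
    tp = sum(c[0] for c in per_subtype_counts.values())
    fp = sum(c[1] for c in per_subtype_counts.values())
    fn = sum(c[2] for c in per_subtype_counts.values())
    return prf(tp, fp, fn)


def evaluate(predicted: Labels, gold: Labels,
             ftc_reassign: Iterable[str] | None = None) -> EvaluationReport:
    """Full evaluation report over all four subtypes plus the micro row.

    ``ftc_reassign`` optionally lists pmids whose gold labels should
    additionally include FTC before scoring.  This reproduces the
    adjusted-FTC analysis for differentiated-thyroid-cancer articles
    that the gold standard annotates as PTC only: a caller who has
    identified such documents can count FTC predictions on them as
    correct instead of as false positives.
    """
    if ftc_reassign:
        reassign = set(ftc_reassign)
        gold = {
            pmid: (labels | {"FTC"} if pmid in reassign else labels)
            for pmid, labels in gold.items()
        }
    per_subtype: dict[str, SubtypeMetrics] = {}
    counts: dict[str, tuple[int, int, int, int]] = {}
    for j in SUBTYPES:
        tp, fp, fn, tn = confusion_counts(predicted, gold, j)
        counts[j] = (tp, fp, fn, tn)
        per_subtype[j] = SubtypeMetrics(tp, fp, fn, tn, *prf(tp, fp, fn))
    mtp = sum(c[0] for c in counts.values())
    mfp = sum(c[1] for c in counts.values())
    mfn = sum(c[2] for c in counts.values())
    mtn = sum(c[3] for c in counts.values())
    micro = SubtypeMetrics(mtp, mfp, mfn, mtn, *prf(mtp, mfp, mfn))
    return EvaluationReport(per_subtype, micro)
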