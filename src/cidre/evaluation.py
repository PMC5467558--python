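"""Micro-averaged precision / recall / F-score over document-level pairs.

Counts are taken over (doc_id, chem_id, dis_id) triples; documents present in
only one of the two sides contribute false positives or false negatives.
Undefined ratios are reported as 0 (flagged), never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False
    undefined_recall: bool = False
    per_document: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def format_table(self) -> str:
        lines = [
            f"{'TP':>10} {'FP':>10} {'FN':>10} {'P':>8} {'R':>8} {'F':>8}",
            f"{self.tp:>10d} {self.fp:>10d} {self.fn:>10d} "
            f"{self.precision:>8.4f} {self.recall:>8.4f} {self.f1:>8.4f}",
        ]
        return "\n".join(lines)


def evaluate(
    predictions: Mapping[str, set[tuple[str, str]]],
    gold: Mapping[str, set[tuple[str, str]]],
) -> EvalReport:
    tp = fp = fn = 0
    per_doc: dict[str, tuple[int, int, int]] = {}
    for doc_id in sorted(set(predictions) | set(gold)):
        p = predictions.get(doc_id, set())
        g = gold.get(doc_id, set())
        dtp = len(p & g)
        dfp = len(p - g)
        dfn = len(g - p)
        per_doc[doc_id] = (dtp, dfp, dfn)
        tp += dtp
        fp += dfp
        fn += dfn
    undef_p = (tp + fp) == 0
    undef_r = (tp + fn) == 0
    precision = 0.0 if undef_p else tp / (tp + fp)
    recall = 0.0 if undef_r else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined_precision=undef_p,
        undefined_recall=undef_r,
        per_document=per_doc,
    )


def write_report(report: EvalReport, stream) -> None:
    """Machine-readable key=value dump."""
    for key, value in report.as_dict().items():
        stream.write(f"{key}={value}\n")
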