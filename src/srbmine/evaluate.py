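"""Mention-level evaluation of a gene recognizer against gold annotations.

Scores exact-span matches: a predicted mention is a true positive iff a
gold mention with identical (doc_id, start, end, locus_tag) exists, each
gold mention consumed at most once.  Besides corpus-level precision,
recall and F1, the harness partitions documents into slices and reports
the per-slice scores with their mean and best F1 — the protocol behind
mean/best F1 comparisons of recognizers.

The 0/0 convention: precision and recall are 0 when their denominator is
0, and F1 is 0 whenever TP = 0.  Exact-span scoring gives no partial
credit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import AnnotatedDocument

__all__ = ["EvalResult", "evaluate_mentions", "slice_eval"]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_slice: list["EvalResult"] = field(default_factory=list)
    mean_f1: float | None = None
    best_f1: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }
        if self.per_slice:
            d["per_slice"] = [s.to_dict() for s in self.per_slice]
            d["mean_f1"] = self.mean_f1
            d["best_f1"] = self.best_f1
        return d


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def evaluate_mentions(
    gold: Sequence[AnnotatedDocument], predicted: Sequence[AnnotatedDocument]
) -> EvalResult:
    """Exact-span mention scoring over aligned document sets.

    Raises ``ValueError`` if the two sides carry different doc_id sets.
    """
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in predicted}
    if set(gold_by_id) != set(pred_by_id):
        missing = set(gold_by_id) ^ set(pred_by_id)
        raise ValueError(f"gold/predicted doc_id mismatch: {sorted(missing)}")
    tp = fp = fn = 0
    for doc_id, g in gold_by_id.items():
        gold_keys = Counter((m.start, m.end, m.locus_tag) for m in g.mentions)
        pred_keys = Counter(
            (m.start, m.end, m.locus_tag) for m in pred_by_id[doc_id].mentions
        )
        matched = sum((gold_keys & pred_keys).values())
        tp += matched
        fp += sum(pred_keys.values()) - matched
        fn += sum(gold_keys.values()) - matched
    p, r, f = _prf(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f)


def slice_eval(
    gold: Sequence[AnnotatedDocument],
    predicted: Sequence[AnnotatedDocument],
    n_slices: int,
    seed: int = 0,
) -> EvalResult:
    """Evaluate per document slice; report mean and best slice F1.

    Documents are partitioned into ``n_slices`` near-equal groups by a
    seed-determined shuffle of the sorted doc_id list, so results are
    independent of input document order.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if n_slices > len(gold):
        raise ValueError(
            f"n_slices={n_slices} exceeds number of documents ({len(gold)})"
        )
    overall = evaluate_mentions(gold, predicted)  # also validates alignment
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in predicted}
    doc_ids = sorted(gold_by_id)
    rng = np.random.default_rng(seed)
    rng.shuffle(doc_ids)
    slices = np.array_split(np.array(doc_ids, dtype=object), n_slices)
    per_slice = [
        evaluate_mentions(
            [gold_by_id[i] for i in chunk], [pred_by_id[i] for i in chunk]
        )
        for chunk in slices
    ]
    overall.per_slice = per_slice
    f1s = [s.f1 for s in per_slice]
    overall.mean_f1 = float(np.mean(f1s))
    overall.best_f1 = float(np.max(f1s))
    return overall
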