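"""Corpus-level scoring of predicted answer sets against gold.

Three metric modes decide what counts as a unit of agreement:

* **extracted_mentions** — every occurrence counts: per document and variant
  key, matched units are ``min(pred multiplicity, gold multiplicity)``, so a
  variant mentioned twice must be extracted twice for a perfect score;
* **normalized_mutations** — a variant counts once per document however often
  it is mentioned (set matching of canonical keys);
* **document_retrieval** — binary per-document: does the document contain
  any variant at all.

Counts are pooled over all documents before the ratios are computed
(micro-averaging), yielding a single corpus-level precision / recall / F1:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .corpus_io import AnswerSet

__all__ = ["Metric", "EvaluationResult", "score", "diff"]


class Metric(str, enum.Enum):
    EXTRACTED_MENTIONS = "extracted_mentions"
    NORMALIZED_MUTATIONS = "normalized_mutations"
    DOCUMENT_RETRIEVAL = "document_retrieval"

    @classmethod
    def coerce(cls, value: "Metric | str") -> "Metric":
        if isinstance(value, cls):
            return value
        aliases = {
            "mentions": cls.EXTRACTED_MENTIONS,
            "normalized": cls.NORMALIZED_MUTATIONS,
            "document": cls.DOCUMENT_RETRIEVAL,
        }
        try:
            return aliases.get(value) or cls(value)
        except ValueError:
            raise ValueError(f"unknown metric {value!r}") from None


@dataclass(frozen=True)
class EvaluationResult:
    """TP/FP/FN counts and micro-averaged precision, recall, F1.

    Zero-denominator convention: a ratio whose denominator is zero is 1.0
    when the opposing side is also empty (a perfectly-empty corpus is
    perfect) and 0.0 otherwise; F1 is 0.0 when precision + recall is zero.
    """

    metric: Metric
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0 if self.fp == 0 else 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "metric": self.metric.value, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def _all_docs(pred: AnswerSet, gold: AnswerSet) -> list[str]:
    return sorted(set(pred.docs()) | set(gold.docs()))


def score(pred: AnswerSet, gold: AnswerSet,
          metric: Metric | str = Metric.NORMALIZED_MUTATIONS,
          ) -> EvaluationResult:
    """Score ``pred`` against ``gold`` under the chosen metric mode."""
    metric = Metric.coerce(metric)
    tp = fp = fn = 0
    for doc_id in _all_docs(pred, gold):
        pk, gk = pred.keys(doc_id), gold.keys(doc_id)
        if metric is Metric.EXTRACTED_MENTIONS:
            for key in pk | gk:
                pm = pred.multiplicity(doc_id, key)
                gm = gold.multiplicity(doc_id, key)
                tp += min(pm, gm)
                fp += max(pm - gm, 0)
                fn += max(gm - pm, 0)
        elif metric is Metric.NORMALIZED_MUTATIONS:
            tp += len(pk & gk)
            fp += len(pk - gk)
            fn += len(gk - pk)
        else:  # DOCUMENT_RETRIEVAL
            p, g = bool(pk), bool(gk)
            tp += int(p and g)
            fp += int(p and not g)
            fn += int(g and not p)
    return EvaluationResult(metric=metric, tp=tp, fp=fp, fn=fn)


def diff(pred: AnswerSet, gold: AnswerSet,
         ) -> dict[str, dict[str, list[str]]]:
    """Per-document partition of canonical keys into TP / FP / FN lists.

    ``TP ∪ FP`` equals the predicted keys and ``TP ∪ FN`` the gold keys of
    each document; supports false-positive / false-negative error analysis.
    """
    out: dict[str, dict[str, list[str]]] = {}
    for doc_id in _all_docs(pred, gold):
        pk, gk = pred.keys(doc_id), gold.keys(doc_id)
        out[doc_id] = {
            "tp": sorted(pk & gk),
            "fp": sorted(pk - gk),
            "fn": sorted(gk - pk),
        }
    return out
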