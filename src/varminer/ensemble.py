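"""Ensemble combiners over normalized answer sets.

Two classic combiners for entity-extraction systems:

* **simple merging** keeps a variant found by at least one input system
  (per-document union of canonical keys) — maximises recall;
* **majority voting** keeps a variant found by at least ``quorum`` systems
  (default 2, i.e. two-of-three agreement) — maximises precision.

Identity is the level-aware canonical key, so a protein-level and a
DNA-level description of the same event remain distinct.  Documents absent
from some inputs count as empty sets for those inputs.  Presence is counted
once per input system regardless of mention multiplicity; the merged
multiplicity is the maximum over the contributing inputs.
"""

from __future__ import annotations

from .corpus_io import AnswerSet

__all__ = ["simple_merge", "majority_vote"]


def _merged_docs(answersets: list[AnswerSet]) -> list[str]:
    docs: set[str] = set()
    for a in answersets:
        docs.update(a.docs())
    return sorted(docs)


def _combine(answersets: list[AnswerSet], quorum: int) -> AnswerSet:
    out = AnswerSet()
    for doc_id in _merged_docs(answersets):
        out.add_document(doc_id)
        votes: dict[str, list[int]] = {}
        for i, a in enumerate(answersets):
            for key in a.keys(doc_id):
                votes.setdefault(key, []).append(i)
        for key in sorted(votes):
            contributors = votes[key]
            if len(contributors) < quorum:
                continue
            mult = max(answersets[i].multiplicity(doc_id, key)
                       for i in contributors)
            entry = answersets[contributors[0]].entries(doc_id)[key]
            out.add(doc_id, entry.variant, multiplicity=mult)
            dest = out.entries(doc_id)[key]
            for i in contributors:
                for src in answersets[i].entries(doc_id)[key].sources or [f"input{i}"]:
                    if src not in dest.sources:
                        dest.sources.append(src)
    return out


def simple_merge(answersets: list[AnswerSet]) -> AnswerSet:
    """Union combiner: a variant extracted by at least one input survives."""
    if not answersets:
        raise ValueError("simple_merge requires at least one answer set")
    return _combine(answersets, quorum=1)


def majority_vote(answersets: list[AnswerSet], quorum: int = 2) -> AnswerSet:
    """Quorum combiner: a variant must be extracted by >= ``quorum`` inputs.

    With three inputs and the default quorum of 2 this is two-of-three
    majority voting; ``quorum=1`` degenerates to :func:`simple_merge`.
    """
    if len(answersets) < 2:
        raise ValueError("majority_vote requires at least two answer sets")
    if quorum < 1:
        raise ValueError("quorum must be >= 1")
    if quorum > len(answersets):
        raise ValueError(
            f"quorum {quorum} exceeds the number of inputs {len(answersets)}")
    return _combine(answersets, quorum=quorum)
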