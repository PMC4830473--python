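"""Documents and the unified answer-set format.

Different extraction tools emit their results in incompatible layouts; the
unified dialect used here is a TSV with one row per (document, normalized
variant): columns ``doc_id, level, kind, wild, position, mutant, rs_id,
multiplicity, surfaces, source``.  Repetition of a variant within a document
is carried by the multiplicity column, never by duplicate rows, and files are
written deterministically (documents sorted by id, variants by canonical key)
so that equal answer sets are byte-identical on disk.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .mention_extraction import Document, VariantMention
from .nomenclature import Kind, Level, NormalizedVariant, canonical_key

__all__ = [
    "AnswerEntry",
    "AnswerSet",
    "AnswerSetFormatError",
    "read_answerset",
    "write_answerset",
    "read_documents",
    "write_documents",
]

COLUMNS = ["doc_id", "level", "kind", "wild", "position", "mutant", "rs_id",
           "multiplicity", "surfaces", "source"]


class AnswerSetFormatError(ValueError):
    """Malformed unified-dialect row; carries the row number and field."""


@dataclass
class AnswerEntry:
    variant: NormalizedVariant
    multiplicity: int = 1
    surfaces: list[str] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


class AnswerSet:
    """Per-document collections of normalized variants with multiplicities.

    Keys within a document are canonical variant keys and unique; adding the
    same variant twice accumulates multiplicity.
    """

    def __init__(self) -> None:
        self._docs: dict[str, dict[str, AnswerEntry]] = {}
        self.warnings: list[str] = []

    # -- construction ------------------------------------------------------

    def add(self, doc_id: str, variant: NormalizedVariant, *,
            multiplicity: int = 1, surface: str | None = None,
            source: str | None = None) -> None:
        if not doc_id:
            raise ValueError("doc_id must be non-empty")
        entries = self._docs.setdefault(doc_id, {})
        key = canonical_key(variant)
        if key in entries:
            e = entries[key]
            e.multiplicity += multiplicity
            if surface:
                e.surfaces.append(surface)
            if source and source not in e.sources:
                e.sources.append(source)
        else:
            entries[key] = AnswerEntry(
                variant=variant, multiplicity=multiplicity,
                surfaces=[surface] if surface else [],
                sources=[source] if source else [],
            )

    def add_document(self, doc_id: str) -> None:
        """Register a document with (so far) no variants."""
        self._docs.setdefault(doc_id, {})

    @classmethod
    def from_mentions(cls, mentions: Iterable[VariantMention],
                      source: str | None = None) -> "AnswerSet":
        """Collect the informative mentions into an answer set."""
        out = cls()
        for m in mentions:
            v = m.normalized
            if v is not None:
                out.add(m.doc_id, v, surface=m.surface, source=source)
        return out

    # -- access ------------------------------------------------------------

    def docs(self) -> list[str]:
        return sorted(self._docs)

    def keys(self, doc_id: str) -> set[str]:
        return set(self._docs.get(doc_id, {}))

    def entries(self, doc_id: str) -> dict[str, AnswerEntry]:
        return self._docs.get(doc_id, {})

    def multiplicity(self, doc_id: str, key: str) -> int:
        entry = self._docs.get(doc_id, {}).get(key)
        return entry.multiplicity if entry else 0

    def n_variants(self) -> int:
        return sum(len(v) for v in self._docs.values())

    def n_mentions(self) -> int:
        return sum(e.multiplicity for v in self._docs.values()
                   for e in v.values())

    def __iter__(self) -> Iterator[tuple[str, str, AnswerEntry]]:
        for doc_id in self.docs():
            for key in sorted(self._docs[doc_id]):
                yield doc_id, key, self._docs[doc_id][key]

    def __len__(self) -> int:
        return self.n_variants()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnswerSet):
            return NotImplemented
        # documents without variants carry no information in the dialect
        return {
            d: {k: e.multiplicity for k, e in v.items()}
            for d, v in self._docs.items() if v
        } == {
            d: {k: e.multiplicity for k, e in v.items()}
            for d, v in other._docs.items() if v
        }

    def copy(self) -> "AnswerSet":
        out = AnswerSet()
        for doc_id, key, e in self:
            out.add(doc_id, e.variant, multiplicity=e.multiplicity)
            out._docs[doc_id][key].surfaces = list(e.surfaces)
            out._docs[doc_id][key].sources = list(e.sources)
        for doc_id in self._docs:
            out.add_document(doc_id)
        return out


# ---------------------------------------------------------------------------
# Unified dialect reader / writer
# ---------------------------------------------------------------------------

def _parse_row(row: dict[str, str], rownum: int) -> tuple[str, AnswerEntry]:
    doc_id = (row.get("doc_id") or "").strip()
    if not doc_id:
        raise AnswerSetFormatError(f"row {rownum}: empty doc_id")
    try:
        pos = row.get("position", "") or ""
        variant = NormalizedVariant(
            level=Level(row["level"]),
            kind=Kind(row["kind"]),
            wild=row.get("wild", "") or "",
            position=int(pos) if pos else None,
            mutant=row.get("mutant", "") or "",
            rs_id=row.get("rs_id", "") or "",
        )
    except (KeyError, ValueError) as exc:
        raise AnswerSetFormatError(f"row {rownum}: {exc}") from exc
    mult_raw = (row.get("multiplicity") or "1").strip()
    try:
        mult = int(mult_raw)
    except ValueError as exc:
        raise AnswerSetFormatError(
            f"row {rownum}: bad multiplicity {mult_raw!r}") from exc
    surfaces = [s for s in (row.get("surfaces") or "").split(";") if s]
    sources = [s for s in (row.get("source") or "").split(";") if s]
    try:
        return doc_id, AnswerEntry(variant=variant, multiplicity=mult,
                                   surfaces=surfaces, sources=sources)
    except ValueError as exc:
        raise AnswerSetFormatError(f"row {rownum}: {exc}") from exc


def read_answerset(path: str | Path) -> AnswerSet:
    """Read a unified-dialect TSV file.

    Duplicate (document, variant) rows are merged with summed multiplicity
    and recorded in ``AnswerSet.warnings``.
    """
    path = Path(path)
    out = AnswerSet()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        missing = {"doc_id", "level", "kind"} - set(reader.fieldnames)
        if missing:
            raise AnswerSetFormatError(
                f"{path}: missing required columns {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            doc_id, entry = _parse_row(row, rownum)
            key = canonical_key(entry.variant)
            if key in out.keys(doc_id):
                out.warnings.append(
                    f"row {rownum}: duplicate ({doc_id}, {key}) merged")
            out.add(doc_id, entry.variant, multiplicity=entry.multiplicity)
            for s in entry.surfaces:
                out._docs[doc_id][key].surfaces.append(s)
            for s in entry.sources:
                if s not in out._docs[doc_id][key].sources:
                    out._docs[doc_id][key].sources.append(s)
    return out


def write_answerset(answers: AnswerSet, path: str | Path) -> None:
    """Write deterministically: docs by id, variants by canonical key."""
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    for doc_id, key, e in answers:
        v = e.variant
        writer.writerow([
            doc_id, v.level.value, v.kind.value, v.wild,
            "" if v.position is None else v.position, v.mutant, v.rs_id,
            e.multiplicity, ";".join(e.surfaces), ";".join(sorted(e.sources)),
        ])
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Documents
# ---------------------------------------------------------------------------

def read_documents(path: str | Path) -> list[Document]:
    """Read documents from a directory of ``.txt`` files (doc_id = stem) or
    a JSON-lines file of ``{"doc_id": ..., "text": ...}`` records."""
    path = Path(path)
    docs: list[Document] = []
    if path.is_dir():
        for p in sorted(path.glob("*.txt")):
            docs.append(Document(doc_id=p.stem, text=p.read_text("utf-8")))
    else:
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    docs.append(Document(doc_id=rec["doc_id"],
                                         text=rec["text"]))
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"{path}: bad JSON-lines record "
                                     f"at line {i}: {exc}") from exc
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r}")
        seen.add(d.doc_id)
    return sorted(docs, key=lambda d: d.doc_id)


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSON-lines (stable order by doc_id)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in sorted(docs, key=lambda d: d.doc_id):
            fh.write(json.dumps({"doc_id": d.doc_id, "text": d.text},
                                ensure_ascii=False) + "\n")
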