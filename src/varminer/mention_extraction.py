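"""Rule-based detection of variant mentions in raw text.

The detector runs an ordered catalogue of named regular-expression patterns
(shipped as ``data/patterns.yaml``, user-extendable) over a document, resolves
overlaps longest-match-first, and attempts to parse every match into a
:class:`~varminer.nomenclature.NormalizedVariant`.  Mentions that assert a
variant without carrying enough information to normalize it (e.g. "valine 600
is mutated") are kept but flagged non-informative, so the post-processing
stage can count and remove them.

Covered surface forms: compact wNm (``T790M``), three-letter wNm
(``Thr790Met``), hyphenated and minus-as-location variants (``Arg-23-Thr``,
``Arg-23Thr``), natural-language substitutions ("substitution of alanine for
proline at amino acid 286"), nucleotide changes ("G>A polymorphism at
nucleotide 5557", ``c.5557G>A``, ``1691G > A``), codon-indexed changes with
explicit codons ("A to G transition at codon 557 (AAG->GAG)"), dbSNP rsIDs,
and keyword-anchored deletions / insertions / frameshifts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .nomenclature import (
    AA_ALPHABET,
    STOP_SYMBOL,
    Kind,
    Level,
    NormalizedVariant,
    UnknownResidueError,
    aa_to_one,
    translate_codon,
)

__all__ = [
    "Document",
    "ParsedChange",
    "VariantMention",
    "MentionExtractor",
    "extract_mentions",
    "parse_mention",
    "load_pattern_catalogue",
]


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class ParsedChange:
    """Partially parsed variant: the fields a surface form actually carries.

    A mention like "replacement of lysine by glutamic acid" yields wild/mutant
    but no position; :meth:`to_variant` returns ``None`` for such incomplete
    substitutions, which downstream code treats as the non-informative marker.
    """

    level: Level
    kind: Kind
    wild: str = ""
    position: int | None = None
    mutant: str = ""
    rs_id: str = ""

    def to_variant(self) -> NormalizedVariant | None:
        if self.kind is Kind.SUB:
            if not (self.wild and self.mutant and self.position is not None):
                return None
        if self.kind is Kind.SNP and not self.rs_id:
            return None
        if self.kind in (Kind.DEL, Kind.INS, Kind.FS, Kind.INDEL, Kind.DUP):
            if self.position is None:
                return None
        try:
            return NormalizedVariant(
                level=self.level, kind=self.kind, wild=self.wild,
                position=self.position, mutant=self.mutant, rs_id=self.rs_id,
            )
        except ValueError:
            return None


@dataclass(frozen=True)
class VariantMention:
    """A located variant mention: exact span, form category, parse result.

    ``normalized`` is ``None`` when the surface does not carry enough
    information to produce a wNm-form variant (the non-informative marker).
    """

    doc_id: str
    start: int
    end: int
    surface: str
    form: str
    pattern: str = ""
    parsed: ParsedChange | None = None

    @property
    def normalized(self) -> NormalizedVariant | None:
        return self.parsed.to_variant() if self.parsed is not None else None

    @property
    def is_informative(self) -> bool:
        return self.normalized is not None


# ---------------------------------------------------------------------------
# Pattern catalogue
# ---------------------------------------------------------------------------

_THREE_LETTER = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly",
                 "His", "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser",
                 "Thr", "Trp", "Tyr", "Val"]
_FULL_NAMES = ["aspartic acid", "glutamic acid", "phenylalanine",
               "isoleucine", "asparagine", "methionine", "tryptophan",
               "glutamine", "histidine", "threonine", "aspartate",
               "glutamate", "arginine", "cysteine", "tyrosine", "alanine",
               "glycine", "leucine", "proline", "serine", "lysine", "valine"]


def _ci_word(word: str) -> str:
    # case-insensitive on the first letter only; internal spaces flexible
    first, rest = word[0], word[1:]
    rest = rest.replace(" ", r"\s+")
    return f"[{first.upper()}{first.lower()}]{rest}"


_AA3 = "(?:" + "|".join(_ci_word(w) for w in _THREE_LETTER) + ")"
_NAME = "(?:" + "|".join(_ci_word(w) for w in _FULL_NAMES) + ")"
_AA1 = f"[{AA_ALPHABET}]"
_AANY = f"(?:{_NAME}|{_AA3}|{_AA1})"
_BASE = "[ACGTU]"
# arrow glyphs seen in the wild, including the en-dash / greater-or-equal
# artefacts that full-text extraction produces from "->" arrows
_ARROW = r"(?:[–−—-]{1,2}\s*[≥>]|⇒|→|=>|[≥>])"
_TO = rf"(?:\s*[–−—-]?\s*to\s*[–−—-]?\s*|\s*{_ARROW}\s*)"

_PLACEHOLDERS = {
    "AA1": _AA1, "AA3": _AA3, "NAME": _NAME, "AANY": _AANY,
    "BASE": _BASE, "ARROW": _ARROW, "TO": _TO,
}


@dataclass(frozen=True)
class Pattern:
    name: str
    form: str
    parser: str
    regex: re.Pattern
    level: str = "p"
    priority: int = 0


def _expand(pattern: str) -> str:
    return re.sub(
        r"\{(AA1|AA3|AANY|NAME|BASE|ARROW|TO)\}",
        lambda m: _PLACEHOLDERS[m.group(1)],
        pattern,
    )


def load_pattern_catalogue(path: str | Path | None = None) -> list[Pattern]:
    """Load the ordered pattern catalogue (bundled by default)."""
    if path is None:
        ref = resources.files("varminer.data") / "patterns.yaml"
        raw = ref.read_text(encoding="utf-8")
    else:
        raw = Path(path).read_text(encoding="utf-8")
    spec = yaml.safe_load(raw)
    catalogue = []
    for i, entry in enumerate(spec["patterns"]):
        catalogue.append(Pattern(
            name=entry["name"],
            form=entry["form"],
            parser=entry["parser"],
            regex=re.compile(_expand(entry["pattern"])),
            level=entry.get("level", "p"),
            priority=i,
        ))
    return catalogue


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class MentionExtractor:
    """Detects and parses variant mentions using the pattern catalogue.

    Parameters
    ----------
    patterns:
        Ordered catalogue; defaults to the bundled one.
    minus_is_location:
        Interpretation of the minus sign in forms like ``Arg-23Thr``: when
        true (default) the position is the upstream location −23, otherwise
        plain 23.  ``Arg-23-Thr`` is unaffected (hyphens are separators).
    """

    def __init__(self, patterns: list[Pattern] | None = None, *,
                 minus_is_location: bool = True) -> None:
        self.patterns = patterns if patterns is not None else load_pattern_catalogue()
        self.minus_is_location = minus_is_location

    # -- detection ---------------------------------------------------------

    def extract(self, doc: Document) -> list[VariantMention]:
        """All non-overlapping mentions, longest-match-wins, sorted by start."""
        candidates: list[tuple[int, int, Pattern, re.Match]] = []
        for pat in self.patterns:
            for m in pat.regex.finditer(doc.text):
                if m.start() < m.end():
                    candidates.append((m.start(), m.end(), pat, m))
        # longest first; catalogue order breaks ties; then leftmost
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2].priority, c[0]))
        chosen: list[tuple[int, int, Pattern, re.Match]] = []
        occupied: list[tuple[int, int]] = []
        for start, end, pat, m in candidates:
            if any(start < e and s < end for s, e in occupied):
                continue
            occupied.append((start, end))
            chosen.append((start, end, pat, m))
        chosen.sort(key=lambda c: c[0])
        return [
            VariantMention(
                doc_id=doc.doc_id, start=s, end=e,
                surface=doc.text[s:e], form=pat.form, pattern=pat.name,
                parsed=self._parse_match(pat, m),
            )
            for s, e, pat, m in chosen
        ]

    def parse_surface(self, surface: str, form: str) -> ParsedChange | None:
        """Parse a bare surface string known to belong to a form category."""
        for pat in self.patterns:
            if pat.form != form:
                continue
            m = pat.regex.fullmatch(surface)
            if m is not None:
                return self._parse_match(pat, m)
        return None

    # -- parsing -----------------------------------------------------------

    def _parse_match(self, pat: Pattern, m: re.Match) -> ParsedChange | None:
        handler = getattr(self, f"_parse_{pat.parser}", None)
        if handler is None:
            raise ValueError(f"unknown parser {pat.parser!r} for {pat.name!r}")
        try:
            return handler(pat, m)
        except (UnknownResidueError, ValueError, KeyError):
            return None

    @staticmethod
    def _named(m: re.Match, name: str) -> str | None:
        return m.groupdict().get(name)

    def _parse_wnm(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(
            level=Level.PROTEIN, kind=Kind.SUB,
            wild=aa_to_one(m.group("w")),
            position=int(m.group("pos")),
            mutant=aa_to_one(m.group("m")),
        )

    def _parse_minus_location(self, pat: Pattern, m: re.Match) -> ParsedChange:
        pos = int(m.group("pos"))
        if self.minus_is_location:
            pos = -pos
        return ParsedChange(
            level=Level.PROTEIN, kind=Kind.SUB,
            wild=aa_to_one(m.group("w")), position=pos,
            mutant=aa_to_one(m.group("m")),
        )

    def _parse_protein_sub_nl(self, pat: Pattern, m: re.Match) -> ParsedChange:
        pos = self._named(m, "pos")
        return ParsedChange(
            level=Level.PROTEIN, kind=Kind.SUB,
            wild=aa_to_one(m.group("w")),
            position=int(pos) if pos else None,
            mutant=aa_to_one(m.group("m")),
        )

    def _parse_non_informative(self, pat: Pattern, m: re.Match) -> None:
        return None

    def _parse_codon_pair(self, pat: Pattern, m: re.Match) -> ParsedChange:
        wild = translate_codon(m.group("wcodon"))
        mutant = translate_codon(m.group("mcodon"))
        # the index is the codon (amino-acid) position; bases never bind to it
        return ParsedChange(
            level=Level.PROTEIN, kind=Kind.SUB,
            wild=wild, position=int(m.group("pos")), mutant=mutant,
        )

    def _parse_dna_sub(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(
            level=Level(pat.level), kind=Kind.SUB,
            wild=m.group("w").upper().replace("U", "T"),
            position=int(m.group("pos")),
            mutant=m.group("m").upper().replace("U", "T"),
        )

    _parse_dna_sub_posfirst = _parse_dna_sub

    def _parse_dbsnp(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(level=Level.DNA, kind=Kind.SNP,
                            rs_id="rs" + m.group("num"))

    def _parse_protein_del(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(level=Level.PROTEIN, kind=Kind.DEL,
                            wild=aa_to_one(m.group("w")),
                            position=int(m.group("pos")))

    def _parse_dna_del(self, pat: Pattern, m: re.Match) -> ParsedChange:
        w = self._named(m, "w") or ""
        return ParsedChange(level=Level.DNA, kind=Kind.DEL,
                            wild=w.upper(), position=int(m.group("pos")))

    def _parse_dna_ins(self, pat: Pattern, m: re.Match) -> ParsedChange:
        # inserted bases may be multi-character; the canonical record keeps
        # kind and position only
        return ParsedChange(level=Level.DNA, kind=Kind.INS,
                            position=int(m.group("pos")))

    def _parse_protein_fs(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(level=Level.PROTEIN, kind=Kind.FS,
                            wild=aa_to_one(m.group("w")),
                            position=int(m.group("pos")))

    def _parse_fs_nl(self, pat: Pattern, m: re.Match) -> ParsedChange:
        return ParsedChange(level=Level.PROTEIN, kind=Kind.FS,
                            position=int(m.group("pos")))


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------

_DEFAULT_EXTRACTOR: MentionExtractor | None = None


def _default_extractor() -> MentionExtractor:
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = MentionExtractor()
    return _DEFAULT_EXTRACTOR


def extract_mentions(doc: Document) -> list[VariantMention]:
    """Extract all variant mentions from a document (default catalogue)."""
    return _default_extractor().extract(doc)


def parse_mention(surface: str, form: str) -> NormalizedVariant | None:
    """Parse a surface string of a known form category to a normalized
    variant, or ``None`` (the non-informative marker) when the surface does
    not carry wild-type, position and mutant."""
    parsed = _default_extractor().parse_surface(surface, form)
    return parsed.to_variant() if parsed is not None else None
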