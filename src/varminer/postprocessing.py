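"""Seven-rule post-processing of variant mentions and answer sets.

Extraction tools share a small set of systematic failure modes: they pick up
mutation-like decoys (cell lines such as T47D, array platforms such as U133A,
supplementary-figure labels), keep mentions that cannot be normalized, parse
hyphens and prepositions the wrong way around, and mis-anchor wild-type
tokens next to explicit nucleotide changes.  The rules here address each:

corrections (applied first, so that corrected forms are what gets judged)
  5. imbalanced-form re-anchoring  — "V 1691G" next to "1691G > A"
  6. special-symbol disambiguation — "Arg-23-Thr" (hyphen) vs "Arg-23Thr"
     (minus denotes location)
  7. "for"-preposition inversion   — in "substitution of X for Y", Y is the
     wild type

filters (pure removals; they never add variants)
  1. lexicon filter                — cell-line / gene / platform / decoy names
  2. non-informative filter        — mentions not convertible to wNm form
  3. substitution-matrix filter    — implausible amino-acid substitutions
  4. synonymous filter             — wild type equals mutant (e.g. L367L)

Every mention receives exactly one terminal :class:`FilterOutcome`, so
``len(input) == len(survivors) + len(removed)`` always holds.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .corpus_io import AnswerSet
from .mention_extraction import (
    _ARROW,
    Document,
    MentionExtractor,
    ParsedChange,
    VariantMention,
)
from .nomenclature import (
    Kind,
    Level,
    NormalizedVariant,
    SubstitutionMatrix,
    load_default_matrix,
)

__all__ = [
    "Rule",
    "Action",
    "FilterOutcome",
    "DecoyPattern",
    "LexiconSet",
    "PostProcessConfig",
    "PostProcessor",
    "load_default_lexicons",
    "filter_mentions",
    "correct_forms",
    "postprocess_answerset",
]


class Rule(str, enum.Enum):
    LEXICON = "lexicon"
    NON_INFORMATIVE = "non_informative"
    SUBSTITUTION_MATRIX = "substitution_matrix"
    SYNONYMOUS = "synonymous"
    IMBALANCED_FORM = "imbalanced_form"
    SPECIAL_SYMBOL = "special_symbol"
    FOR_PREPOSITION = "for_preposition"
    NONE = "none"


class Action(str, enum.Enum):
    REMOVED = "removed"
    MODIFIED = "modified"
    KEPT = "kept"


@dataclass(frozen=True)
class FilterOutcome:
    rule_id: Rule
    action: Action
    before: VariantMention
    after: VariantMention | None
    note: str = ""


@dataclass(frozen=True)
class DecoyPattern:
    """A productive decoy family, e.g. supplementary-figure labels.

    ``surface`` must match the whole mention; ``context``, when given, must
    match at the end of the text preceding the mention (so "Figure " before
    "S13A" marks it as a label, while a bare "S13A" elsewhere may be a
    genuine Ser13Ala)."""

    name: str
    surface: re.Pattern
    context: re.Pattern | None = None

    def matches(self, mention: VariantMention, text: str | None) -> bool:
        if not self.surface.fullmatch(mention.surface):
            return False
        if self.context is None:
            return True
        if text is None:
            return False
        return self.context.search(text[:mention.start]) is not None


_FIGURE_LABEL = DecoyPattern(
    name="figure_label",
    surface=re.compile(r"(?:S\d+[A-Z]?|\d+[A-Z])"),
    context=re.compile(
        r"(?:[Ff]igs?\.?|[Ff]igures?|[Tt]ables?|[Ss]upplementary(?:\s+"
        r"(?:[Ff]igs?\.?|[Ff]igures?|[Tt]ables?))?)\s*$"),
)


def _norm_term(s: str) -> str:
    return " ".join(s.split()).casefold()


@dataclass
class LexiconSet:
    """Mutation-like decoy names: cell lines, gene symbols, platforms."""

    cell_lines: set[str] = field(default_factory=set)
    gene_symbols: set[str] = field(default_factory=set)
    platform_names: set[str] = field(default_factory=set)
    decoy_patterns: list[DecoyPattern] = field(
        default_factory=lambda: [_FIGURE_LABEL])

    def __post_init__(self) -> None:
        self.cell_lines = {_norm_term(s) for s in self.cell_lines}
        self.gene_symbols = {_norm_term(s) for s in self.gene_symbols}
        self.platform_names = {_norm_term(s) for s in self.platform_names}

    def lookup(self, surface: str) -> str | None:
        """Name of the lexicon containing ``surface``, or ``None``."""
        t = _norm_term(surface)
        if t in self.cell_lines:
            return "cell_lines"
        if t in self.gene_symbols:
            return "gene_symbols"
        if t in self.platform_names:
            return "platform_names"
        return None

    def decoy(self, mention: VariantMention,
              text: str | None) -> DecoyPattern | None:
        for pat in self.decoy_patterns:
            if pat.matches(mention, text):
                return pat
        return None


def _read_lexicon_file(path: Path) -> set[str]:
    out = set()
    for line in path.read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def load_default_lexicons() -> LexiconSet:
    """Load the seed lexicons bundled with the package."""
    data = resources.files("varminer.data")
    sets = {}
    for name in ("cell_lines", "gene_symbols", "platform_names"):
        with resources.as_file(data / f"{name}.txt") as p:
            sets[name] = _read_lexicon_file(p)
    return LexiconSet(**sets)


@dataclass
class PostProcessConfig:
    """Per-rule toggles and numeric knobs; every rule is switchable."""

    lexicon: bool = True
    non_informative: bool = True
    substitution_matrix: bool = True
    synonymous: bool = True
    imbalanced_form: bool = True
    special_symbol: bool = True
    for_preposition: bool = True
    matrix_threshold: float | None = None  # None: keep the matrix's own cutoff
    minus_is_location: bool = True

    def enabled(self, rule: Rule) -> bool:
        return getattr(self, rule.value)


# regexes used by the correction rules ------------------------------------

_COMPACT_CHANGE = re.compile(
    rf"\b(?P<pos>\d+)\s*(?P<w>[ACGTU])\s*{_ARROW}\s*(?P<m>[ACGTU])\b")
_SPACED_WNM = re.compile(r"[A-Za-z]{1,3}[\s]+\d+[\s]*[A-Za-z]{0,3}")
_HYPHEN_SURFACE = re.compile(r"\S+[-–−]\d+[-–−]?\S+")
_FOR_SURFACE = re.compile(
    r"(?:[Ss]ubstitution|[Rr]eplacement)s?\s+of\s+.+\s+for\s+.+")


class PostProcessor:
    """Applies corrections (rules 5–7) then filters (rules 1–4)."""

    def __init__(self, lexicons: LexiconSet | None = None,
                 matrix: SubstitutionMatrix | None = None,
                 config: PostProcessConfig | None = None) -> None:
        self.config = config or PostProcessConfig()
        self.lexicons = lexicons if lexicons is not None else load_default_lexicons()
        threshold = self.config.matrix_threshold
        if matrix is None:
            matrix = load_default_matrix(
                threshold=-4.0 if threshold is None else threshold)
        elif threshold is not None and matrix.threshold != threshold:
            matrix = replace(matrix, threshold=threshold)
        self.matrix = matrix
        self._extractor = MentionExtractor(
            minus_is_location=self.config.minus_is_location)

    # -- corrections (rules 5-7) ------------------------------------------

    def correct_forms(self, text: str,
                      mention: VariantMention) -> tuple[VariantMention, FilterOutcome]:
        """Apply rules 5–7 to one mention located in ``text``.

        Un-correctable mentions pass through unchanged with action ``kept``.
        """
        cfg = self.config
        if cfg.imbalanced_form:
            fixed = self._rule5_imbalanced(text, mention)
            if fixed is not None:
                return fixed, FilterOutcome(
                    Rule.IMBALANCED_FORM, Action.MODIFIED, mention, fixed,
                    note=f"re-anchored to explicit change {fixed.surface!r}")
        if cfg.special_symbol and _HYPHEN_SURFACE.fullmatch(mention.surface):
            fixed = self._reparse(mention)
            if fixed is not None:
                return fixed, FilterOutcome(
                    Rule.SPECIAL_SYMBOL, Action.MODIFIED, mention, fixed,
                    note="hyphen/minus semantics re-resolved")
        if cfg.for_preposition and _FOR_SURFACE.fullmatch(mention.surface):
            fixed = self._reparse(mention, form="natural_language")
            if fixed is not None:
                return fixed, FilterOutcome(
                    Rule.FOR_PREPOSITION, Action.MODIFIED, mention, fixed,
                    note="'for' binds its second residue as wild type")
        return mention, FilterOutcome(Rule.NONE, Action.KEPT, mention, mention)

    def _rule5_imbalanced(self, text: str,
                          mention: VariantMention) -> VariantMention | None:
        # A spurious wild-type token with internal whitespace ("V 1691G")
        # adjacent to an explicit change ("1691G > A"): re-anchor the mention
        # to the explicit change and re-normalize at the DNA level.
        if not _SPACED_WNM.fullmatch(mention.surface):
            return None
        lo = max(0, mention.start - 10)
        hi = min(len(text), mention.end + 20)
        for m in _COMPACT_CHANGE.finditer(text, lo, hi):
            if m.start() < mention.end and mention.start < m.end():
                parsed = ParsedChange(
                    level=Level.DNA, kind=Kind.SUB,
                    wild=m.group("w").upper().replace("U", "T"),
                    position=int(m.group("pos")),
                    mutant=m.group("m").upper().replace("U", "T"))
                return VariantMention(
                    doc_id=mention.doc_id, start=m.start(), end=m.end(),
                    surface=text[m.start():m.end()],
                    form="nucleotide_change", pattern="rule5_reanchor",
                    parsed=parsed)
        return None

    def _reparse(self, mention: VariantMention,
                 form: str | None = None) -> VariantMention | None:
        """Re-parse a surface under the canonical grammar; a corrected
        mention is returned only when the parse differs from the current one."""
        forms = [form] if form else ["wnm_long", "wnm_short",
                                     "natural_language"]
        for f in forms:
            parsed = self._extractor.parse_surface(mention.surface, f)
            if parsed is None:
                continue
            if parsed == mention.parsed:
                return None
            return replace(mention, form=f, parsed=parsed)
        return None

    # -- filters (rules 1-4) ----------------------------------------------

    def filter_mentions(
        self, mentions: list[VariantMention], *, text: str | None = None,
    ) -> tuple[list[VariantMention], list[FilterOutcome]]:
        """Apply rules 1–4 in order; every removal is logged."""
        survivors: list[VariantMention] = []
        outcomes: list[FilterOutcome] = []
        for mention in mentions:
            outcome = self._filter_one(mention, text)
            outcomes.append(outcome)
            if outcome.action is not Action.REMOVED:
                survivors.append(mention)
        return survivors, outcomes

    def _filter_one(self, mention: VariantMention,
                    text: str | None) -> FilterOutcome:
        cfg = self.config
        if cfg.lexicon:
            hit = self.lexicons.lookup(mention.surface)
            if hit is not None:
                return FilterOutcome(Rule.LEXICON, Action.REMOVED, mention,
                                     None, note=f"matched {hit} lexicon")
            decoy = self.lexicons.decoy(mention, text)
            if decoy is not None:
                return FilterOutcome(Rule.LEXICON, Action.REMOVED, mention,
                                     None, note=f"decoy pattern {decoy.name}")
        if cfg.non_informative and not mention.is_informative:
            return FilterOutcome(Rule.NON_INFORMATIVE, Action.REMOVED,
                                 mention, None,
                                 note="not convertible to wNm form")
        v = mention.normalized
        if (cfg.substitution_matrix and v is not None
                and v.kind is Kind.SUB and v.level is Level.PROTEIN
                and v.wild in self.matrix.alphabet
                and v.mutant in self.matrix.alphabet
                and not self.matrix.is_plausible(v.wild, v.mutant)):
            return FilterOutcome(
                Rule.SUBSTITUTION_MATRIX, Action.REMOVED, mention, None,
                note=(f"{self.matrix.name}({v.wild},{v.mutant})="
                      f"{self.matrix.score(v.wild, v.mutant):g} < "
                      f"{self.matrix.threshold:g}"))
        if (cfg.synonymous and v is not None and v.kind is Kind.SUB
                and v.wild == v.mutant):
            return FilterOutcome(Rule.SYNONYMOUS, Action.REMOVED, mention,
                                 None, note="wild type equals mutant")
        return FilterOutcome(Rule.NONE, Action.KEPT, mention, mention)

    # -- document / answer-set pipelines ----------------------------------

    def process_mentions(
        self, doc: Document, mentions: list[VariantMention],
    ) -> tuple[list[VariantMention], list[FilterOutcome]]:
        """Corrections then filters over the mentions of one document."""
        log: list[FilterOutcome] = []
        corrected: list[VariantMention] = []
        for mention in mentions:
            fixed, outcome = self.correct_forms(doc.text, mention)
            if outcome.action is Action.MODIFIED:
                log.append(outcome)
            corrected.append(fixed)
        survivors, outcomes = self.filter_mentions(corrected, text=doc.text)
        log.extend(outcomes)
        return survivors, log

    def process_answerset(
        self, answers: AnswerSet,
        documents: dict[str, Document] | None = None,
    ) -> tuple[AnswerSet, list[FilterOutcome]]:
        """Post-process a unified answer set (any tool's output).

        Each row is reconstructed as a pseudo-mention from its recorded
        surfaces (falling back to the compact wNm rendering of the variant),
        corrected against the document text when available, then filtered.
        """
        out = AnswerSet()
        log: list[FilterOutcome] = []
        for doc_id in answers.docs():
            out.add_document(doc_id)
            doc = (documents or {}).get(doc_id)
            for key in sorted(answers.keys(doc_id)):
                entry = answers.entries(doc_id)[key]
                mention = self._pseudo_mention(doc_id, entry, doc)
                if doc is not None:
                    mention, outcome = self.correct_forms(doc.text, mention)
                    if outcome.action is Action.MODIFIED:
                        log.append(outcome)
                else:
                    fixed = self._correct_surface_only(mention)
                    if fixed is not None:
                        log.append(FilterOutcome(
                            Rule.SPECIAL_SYMBOL
                            if _HYPHEN_SURFACE.fullmatch(mention.surface)
                            else Rule.FOR_PREPOSITION,
                            Action.MODIFIED, mention, fixed))
                        mention = fixed
                text = doc.text if doc is not None else None
                outcome = self._filter_one(mention, text)
                log.append(outcome)
                if outcome.action is not Action.REMOVED:
                    v = mention.normalized
                    if v is not None:
                        out.add(doc_id, v, multiplicity=entry.multiplicity)
        return out, log

    def _correct_surface_only(
            self, mention: VariantMention) -> VariantMention | None:
        cfg = self.config
        if cfg.special_symbol and _HYPHEN_SURFACE.fullmatch(mention.surface):
            return self._reparse(mention)
        if cfg.for_preposition and _FOR_SURFACE.fullmatch(mention.surface):
            return self._reparse(mention, form="natural_language")
        return None

    def _pseudo_mention(self, doc_id: str, entry, doc: Document | None
                        ) -> VariantMention:
        v = entry.variant
        surface = entry.surfaces[0] if entry.surfaces else (
            f"{v.wild}{v.position}{v.mutant}"
            if v.kind is Kind.SUB and v.position is not None else v.key)
        start, end = 0, len(surface)
        if doc is not None:
            idx = doc.text.find(surface)
            if idx >= 0:
                start, end = idx, idx + len(surface)
        parsed = ParsedChange(level=v.level, kind=v.kind, wild=v.wild,
                              position=v.position, mutant=v.mutant,
                              rs_id=v.rs_id)
        return VariantMention(doc_id=doc_id, start=start, end=end,
                              surface=surface, form="answerset_row",
                              pattern="answerset_row", parsed=parsed)


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------

def filter_mentions(mentions: list[VariantMention], lexicons: LexiconSet,
                    matrix: SubstitutionMatrix,
                    config: PostProcessConfig | None = None, *,
                    text: str | None = None,
                    ) -> tuple[list[VariantMention], list[FilterOutcome]]:
    proc = PostProcessor(lexicons=lexicons, matrix=matrix, config=config)
    return proc.filter_mentions(mentions, text=text)


def correct_forms(text: str, mention: VariantMention,
                  config: PostProcessConfig | None = None,
                  ) -> tuple[VariantMention, FilterOutcome]:
    proc = PostProcessor(config=config)
    return proc.correct_forms(text, mention)


def postprocess_answerset(answers: AnswerSet,
                          lexicons: LexiconSet | None = None,
                          matrix: SubstitutionMatrix | None = None,
                          config: PostProcessConfig | None = None,
                          documents: dict[str, Document] | None = None,
                          ) -> tuple[AnswerSet, list[FilterOutcome]]:
    proc = PostProcessor(lexicons=lexicons, matrix=matrix, config=config)
    return proc.process_answerset(answers, documents=documents)
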