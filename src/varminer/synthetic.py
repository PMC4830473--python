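"""Seeded generator of synthetic corpora with known gold annotations.

Documents are short sequences of template sentences, each embedding either a
variant realized in one of the catalogued surface forms (compact wNm,
three-letter wNm, natural language, nucleotide change, codon-indexed change
with explicit codons, dbSNP rsID) or a decoy — a mutation-like cell-line
name, a microarray platform name, a supplementary-figure label or a chemical
formula.  The gold answer set lists exactly the embedded variants with their
mention multiplicities, so extraction, post-processing, ensembling and
scoring can all be exercised end-to-end without any external data.

Generation is a pure function of the seed: the same :class:`CorpusSpec`
always yields byte-identical documents and gold.

The module also provides :func:`worked_examples`: a small, hand-curated set
of sentences from published articles (keyed by PMID), each a known hard case
for variant extractors, paired with its correct gold annotation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus_io import AnswerSet
from .mention_extraction import Document
from .nomenclature import (
    AA_ALPHABET,
    ONE_TO_NAME,
    ONE_TO_THREE,
    Kind,
    Level,
    NormalizedVariant,
    SubstitutionMatrix,
    load_default_matrix,
    translate_codon,
)

__all__ = ["CorpusSpec", "generate_corpus", "worked_examples",
           "FORM_CATEGORIES"]

FORM_CATEGORIES = ("wnm_short", "wnm_long", "natural_language",
                   "nucleotide_change", "codon_change", "dbsnp_id")

#: Surface forms roughly matching the mix seen in full-text cancer papers:
#: compact wNm dominates, longer and nucleic forms are rarer.
DEFAULT_FORM_MIX = {
    "wnm_short": 0.45,
    "wnm_long": 0.20,
    "natural_language": 0.15,
    "nucleotide_change": 0.10,
    "codon_change": 0.05,
    "dbsnp_id": 0.05,
}

_VARIANT_TEMPLATES = [
    "We identified the {m} mutation in the tumor samples.",
    "The {m} variant was strongly associated with drug resistance.",
    "Cells carrying {m} showed increased sensitivity to the inhibitor.",
    "Sequencing revealed {m} in three of the patients.",
    "The patients harbored {m} in the kinase domain.",
]

_DECOY_TEMPLATES = {
    "cell_line": "The {d} cells were cultured overnight before treatment.",
    "platform": "Expression was profiled on the {d} array.",
    "figure": "The full results are shown in Supplementary Figure {d}.",
    "formula": "The medium was supplemented with {d} before lysis.",
}

_DECOY_CELL_LINES = ["T47D", "U266", "K562", "A431", "H460", "U937"]
_DECOY_PLATFORMS = ["U133A", "U133B", "U95A", "U219"]
_DECOY_FIGURES = ["S13A", "S10A", "S2B", "S7C"]
_DECOY_FORMULAE = ["C6H12O6", "C2H5OH", "NaCl2", "H2O2"]


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus; generation is pure in ``seed``."""

    seed: int = 0
    n_docs: int = 100
    variants_per_doc: tuple[int, int] = (1, 3)
    form_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FORM_MIX))
    decoy_rate: float = 1.0
    duplicate_mention_rate: float = 0.1
    #: extra non-gold realizations exercising the synonymous and
    #: substitution-matrix filters; off by default
    synonymous_rate: float = 0.0
    implausible_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if any(w < 0 for w in self.form_mix.values()):
            raise ValueError("form_mix weights must be non-negative")
        if not any(w > 0 for w in self.form_mix.values()):
            raise ValueError("form_mix needs at least one positive weight")
        unknown = set(self.form_mix) - set(FORM_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown form categories: {sorted(unknown)}")
        lo, hi = self.variants_per_doc
        if lo < 0 or hi < lo:
            raise ValueError("variants_per_doc must satisfy 0 <= min <= max")


class _Realizer:
    """Samples (variant, surface, form) triples from the form catalogue."""

    def __init__(self, rng: random.Random, matrix: SubstitutionMatrix,
                 lexicon_surfaces: set[str]) -> None:
        self.rng = rng
        self.matrix = matrix
        self.avoid = {s.casefold() for s in lexicon_surfaces}

    def _position(self) -> int:
        return self.rng.randint(1, 2000)

    def _plausible_pair(self) -> tuple[str, str]:
        while True:
            w, m = self.rng.sample(AA_ALPHABET, 2)
            if self.matrix.is_plausible(w, m):
                return w, m

    def _codon_pair(self) -> tuple[str, str, str, str]:
        # single-base codon change that is non-synonymous, non-stop and
        # survives the plausibility filter
        while True:
            wc = "".join(self.rng.choice("ACGT") for _ in range(3))
            i = self.rng.randrange(3)
            b = self.rng.choice([x for x in "ACGT" if x != wc[i]])
            mc = wc[:i] + b + wc[i + 1:]
            w, m = translate_codon(wc), translate_codon(mc)
            if w != m and "*" not in (w, m) and self.matrix.is_plausible(w, m):
                return wc, mc, w, m

    def realize(self, form: str) -> tuple[NormalizedVariant, str]:
        while True:
            variant, surface = self._realize_once(form)
            if surface.casefold() not in self.avoid:
                return variant, surface

    def _realize_once(self, form: str) -> tuple[NormalizedVariant, str]:
        rng = self.rng
        if form == "dbsnp_id":
            rs = f"rs{rng.randint(1000, 99999999)}"
            return (NormalizedVariant(level=Level.DNA, kind=Kind.SNP,
                                      rs_id=rs), rs)
        if form == "nucleotide_change":
            w, m = rng.sample("ACGT", 2)
            pos = self._position()
            variant = NormalizedVariant(level=Level.DNA, kind=Kind.SUB,
                                        wild=w, position=pos, mutant=m)
            surface = rng.choice([
                f"{w}–≥{m} polymorphism at nucleotide {pos}",
                f"{w} to {m} transition at nucleotide {pos}",
                f"c.{pos}{w}>{m}",
                f"{pos}{w} > {m}",
            ])
            return variant, surface
        if form == "codon_change":
            wc, mc, w, m = self._codon_pair()
            i = next(k for k in range(3) if wc[k] != mc[k])
            pos = self._position()
            variant = NormalizedVariant(level=Level.PROTEIN, kind=Kind.SUB,
                                        wild=w, position=pos, mutant=m)
            surface = (f"{wc[i]} to {mc[i]} transition at codon {pos} "
                       f"({wc}–≥{mc})")
            return variant, surface
        # protein-level wNm and natural-language forms
        w, m = self._plausible_pair()
        pos = self._position()
        variant = NormalizedVariant(level=Level.PROTEIN, kind=Kind.SUB,
                                    wild=w, position=pos, mutant=m)
        if form == "wnm_short":
            return variant, f"{w}{pos}{m}"
        if form == "wnm_long":
            return variant, f"{ONE_TO_THREE[w]}{pos}{ONE_TO_THREE[m]}"
        if form == "natural_language":
            wn, mn = ONE_TO_NAME[w], ONE_TO_NAME[m]
            surface = rng.choice([
                f"substitution of {mn} for {wn} at amino acid {pos}",
                f"{wn} {pos} substituted with {mn}",
                f"replacement of {wn} by {mn} at position {pos}",
            ])
            return variant, surface
        raise ValueError(f"unknown form category {form!r}")

    def synonymous_surface(self) -> str:
        w = self.rng.choice(AA_ALPHABET)
        return f"{w}{self._position()}{w}"

    def implausible_surface(self) -> str:
        while True:
            w, m = self.rng.sample(AA_ALPHABET, 2)
            if not self.matrix.is_plausible(w, m):
                return f"{w}{self._position()}{m}"


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], AnswerSet]:
    """Generate documents plus the gold answer set for ``spec``."""
    from .postprocessing import load_default_lexicons  # avoid import cycle

    rng = random.Random(spec.seed)
    matrix = load_default_matrix()
    lex = load_default_lexicons()
    avoid = lex.cell_lines | lex.gene_symbols | lex.platform_names
    realizer = _Realizer(rng, matrix, avoid)
    forms = sorted(spec.form_mix)
    weights = [spec.form_mix[f] for f in forms]

    docs: list[Document] = []
    gold = AnswerSet()
    for i in range(spec.n_docs):
        doc_id = f"synth{i:05d}"
        gold.add_document(doc_id)
        sentences: list[str] = []
        n_var = rng.randint(*spec.variants_per_doc)
        used_keys: set[str] = set()
        for _ in range(n_var):
            form = rng.choices(forms, weights=weights)[0]
            variant, surface = realizer.realize(form)
            while variant.key in used_keys:
                variant, surface = realizer.realize(form)
            used_keys.add(variant.key)
            template = rng.choice(_VARIANT_TEMPLATES)
            sentences.append(template.format(m=surface))
            mult = 1
            if rng.random() < spec.duplicate_mention_rate:
                mult = 2
                sentences.append(
                    rng.choice(_VARIANT_TEMPLATES).format(m=surface))
            gold.add(doc_id, variant, multiplicity=mult, surface=surface)
        n_decoys = _poisson(rng, spec.decoy_rate)
        for _ in range(n_decoys):
            kind = rng.choice(list(_DECOY_TEMPLATES))
            d = rng.choice({
                "cell_line": _DECOY_CELL_LINES,
                "platform": _DECOY_PLATFORMS,
                "figure": _DECOY_FIGURES,
                "formula": _DECOY_FORMULAE,
            }[kind])
            sentences.append(_DECOY_TEMPLATES[kind].format(d=d))
        if rng.random() < spec.synonymous_rate:
            sentences.append(rng.choice(_VARIANT_TEMPLATES).format(
                m=realizer.synonymous_surface()))
        if rng.random() < spec.implausible_rate:
            sentences.append(rng.choice(_VARIANT_TEMPLATES).format(
                m=realizer.implausible_surface()))
        if not sentences:
            sentences.append("No sequence variants were detected in this "
                             "sample.")
        rng.shuffle(sentences)
        docs.append(Document(doc_id=doc_id, text=" ".join(sentences)))
    return docs, gold


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small (decoys per document)
    if lam <= 0:
        return 0
    import math
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Hand-curated worked examples (verbatim sentences from published articles,
# keyed by PMID) with their correct gold annotations.  Each is a documented
# hard case: natural-language "for" binding, mixed DNA/protein levels in one
# sentence, and a codon-indexed base change that must be resolved by codon
# translation rather than by binding the bases to the index.
# ---------------------------------------------------------------------------

_EXAMPLE_SENTENCES = {
    "PMID21080147": (
        "In a patient, a C-to-G transition was identified at nucleotide 857 "
        "in exon 8 that resulted in a substitution of alanine for proline "
        "at amino acid 286 in the first calcium binding EGF domain."
    ),
    "PMID17517479": (
        "Fifteen patients were heterozygous for the G–≥A "
        "polymorphism at nucleotide 5557, which causes substitution of "
        "asparagine for aspartic acid at position 1853 of the ATM protein."
    ),
    "PMID16840830": (
        "The Turkish patient and her affected relatives all had a "
        "heterozygous A to G transition at codon 557 (AAG–≥GAG) "
        "of exon 10 of MEN1 that results in a replacement of lysine by "
        "glutamic acid."
    ),
}

_EXAMPLE_GOLD = {
    "PMID21080147": ["p|SUB|P|286|A"],
    "PMID17517479": ["p|SUB|D|1853|N", "c|SUB|G|5557|A"],
    "PMID16840830": ["p|SUB|K|557|E"],
}

#: Short text fragments exercising the correction rules: an imbalanced
#: wild-type token next to an explicit nucleotide change, hyphen-vs-minus
#: disambiguation, and the "for"-preposition inversion.
_FRAGMENTS = {
    "frag-imbalanced": ("The thrombosis-associated factor V 1691G > A "
                        "variant was genotyped in all cases.",
                        ["c|SUB|G|1691|A"]),
    "frag-hyphen": ("The Arg-23-Thr substitution abolished binding.",
                    ["p|SUB|R|23|T"]),
    "frag-minus-location": ("The promoter variant Arg-23Thr was rare.",
                            ["p|SUB|R|-23|T"]),
    "frag-for-preposition": ("We observed a substitution of arginine for "
                             "methionine at position 12.",
                             ["p|SUB|M|12|R"]),
}


def worked_examples(include_fragments: bool = True,
                    ) -> tuple[list[Document], AnswerSet]:
    """Curated example sentences (doc_id = PMID) with gold annotations."""
    from .nomenclature import parse_key

    docs = [Document(doc_id=k, text=v)
            for k, v in sorted(_EXAMPLE_SENTENCES.items())]
    gold = AnswerSet()
    for doc_id, keys in _EXAMPLE_GOLD.items():
        gold.add_document(doc_id)
        for key in keys:
            gold.add(doc_id, parse_key(key))
    if include_fragments:
        for doc_id, (text, keys) in sorted(_FRAGMENTS.items()):
            docs.append(Document(doc_id=doc_id, text=text))
            gold.add_document(doc_id)
            for key in keys:
                gold.add(doc_id, parse_key(key))
    docs.sort(key=lambda d: d.doc_id)
    return docs, gold
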