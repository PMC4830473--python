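"""Amino-acid and codon translation tables, the normalized-variant data model,
and substitution-matrix scoring.

Every downstream stage — mention parsing, post-processing filters, ensembling
and evaluation — keys on the :class:`NormalizedVariant` produced here, which
encodes a point mutation in the wNm convention (wild-type residue, sequence
position, mutant residue), generalised with a sequence level (protein / coding
DNA / RNA) and a variant kind (substitution, deletion, insertion, ...).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "AA_ALPHABET",
    "STOP_SYMBOL",
    "Level",
    "Kind",
    "NormalizedVariant",
    "SubstitutionMatrix",
    "UnknownResidueError",
    "aa_to_one",
    "translate_codon",
    "matrix_score",
    "canonical_key",
    "parse_key",
    "load_default_matrix",
]

#: The 20 standard amino acids, one-letter codes.  Selenocysteine (U) and
#: pyrrolysine (O) are deliberately excluded: they do not appear in PAM-family
#: matrices and essentially never in mutation mentions.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol returned for stop codons.
STOP_SYMBOL = "*"

NUC_ALPHABET = "ACGTU"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_NAME_TO_ONE = {
    "alanine": "A", "arginine": "R", "asparagine": "N",
    "aspartic acid": "D", "aspartate": "D",
    "cysteine": "C", "glutamine": "Q",
    "glutamic acid": "E", "glutamate": "E",
    "glycine": "G", "histidine": "H", "isoleucine": "I", "leucine": "L",
    "lysine": "K", "methionine": "M", "phenylalanine": "F", "proline": "P",
    "serine": "S", "threonine": "T", "tryptophan": "W", "tyrosine": "Y",
    "valine": "V",
}

# Standard genetic code (DNA codons).  Kept as an explicit table so that the
# test suite can cross-check it against an independent implementation.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP_SYMBOL, "TAG": STOP_SYMBOL,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP_SYMBOL, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


#: Reverse maps used when rendering residues in longer surface forms.
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
ONE_TO_NAME = {v: k for k, v in _NAME_TO_ONE.items()
               if k not in ("aspartate", "glutamate")}


class UnknownResidueError(ValueError):
    """Raised when a token cannot be resolved to a standard residue."""


def aa_to_one(token: str) -> str:
    """Resolve an amino-acid token to its uppercase one-letter code.

    Accepts one-letter codes (``"T"``), three-letter codes (``"Thr"``) and
    full names (``"threonine"``, ``"aspartic acid"``), case-insensitively.
    Unknown tokens raise :class:`UnknownResidueError` rather than guessing.
    """
    if not token:
        raise UnknownResidueError("empty residue token")
    t = " ".join(token.split())  # collapse internal whitespace
    if len(t) == 1:
        u = t.upper()
        if u in AA_ALPHABET:
            return u
        raise UnknownResidueError(f"unknown residue: {token!r}")
    if len(t) == 3:
        u = t.capitalize()
        if u in _THREE_TO_ONE:
            return _THREE_TO_ONE[u]
    name = t.lower()
    if name in _NAME_TO_ONE:
        return _NAME_TO_ONE[name]
    raise UnknownResidueError(f"unknown residue: {token!r}")


def translate_codon(codon: str) -> str:
    """Translate a three-base codon under the standard genetic code.

    ``U`` is folded to ``T``; stop codons return :data:`STOP_SYMBOL`.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    c = codon.upper().replace("U", "T")
    if any(b not in "ACGT" for b in c):
        raise ValueError(f"non-nucleotide character in codon {codon!r}")
    return _CODON_TABLE[c]


class Level(str, enum.Enum):
    """Sequence level of a variant description (HGVS-style prefixes)."""

    PROTEIN = "p"
    DNA = "c"
    RNA = "r"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class Kind(str, enum.Enum):
    SUB = "SUB"
    DEL = "DEL"
    INS = "INS"
    INDEL = "INDEL"
    DUP = "DUP"
    FS = "FS"
    SNP = "SNP"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """Canonical wNm record: wild-type residue/base, position, mutant.

    ``kind=SUB`` requires wild, position and mutant; ``kind=SNP`` identified
    by a dbSNP rsID may leave them empty.  Positions may be negative (the
    upstream-location convention for a minus sign that denotes location).
    """

    level: Level
    kind: Kind
    wild: str = ""
    position: int | None = None
    mutant: str = ""
    rs_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", Level(self.level))
        object.__setattr__(self, "kind", Kind(self.kind))
        alphabet = AA_ALPHABET if self.level is Level.PROTEIN else NUC_ALPHABET
        for name in ("wild", "mutant"):
            v = getattr(self, name)
            if v and (len(v) != 1 or v not in alphabet + STOP_SYMBOL):
                raise ValueError(
                    f"{name}={v!r} not a single {self.level.name}-level code"
                )
        if self.kind is Kind.SUB:
            if not (self.wild and self.mutant and self.position is not None):
                raise ValueError("SUB requires wild, position and mutant")
        if self.kind is Kind.SNP and not self.rs_id:
            if self.position is None:
                raise ValueError("SNP requires an rs_id or a position")

    @property
    def key(self) -> str:
        return canonical_key(self)

    def __str__(self) -> str:
        return self.key


def canonical_key(v: NormalizedVariant) -> str:
    """Deterministic pipe-delimited serialization, e.g. ``p|SUB|T|790|M``.

    The serialization is lossless: :func:`parse_key` inverts it.
    """
    pos = "" if v.position is None else str(v.position)
    parts = [v.level.value, v.kind.value, v.wild, pos, v.mutant]
    if v.kind is Kind.SNP:
        parts.append(v.rs_id)
    return "|".join(parts)


def parse_key(key: str) -> NormalizedVariant:
    """Inverse of :func:`canonical_key`."""
    parts = key.split("|")
    if len(parts) not in (5, 6):
        raise ValueError(f"malformed canonical key: {key!r}")
    level, kind, wild, pos, mutant = parts[:5]
    rs_id = parts[5] if len(parts) == 6 else ""
    return NormalizedVariant(
        level=Level(level),
        kind=Kind(kind),
        wild=wild,
        position=int(pos) if pos else None,
        mutant=mutant,
        rs_id=rs_id,
    )


@dataclass
class SubstitutionMatrix:
    """Square amino-acid log-odds matrix with a plausibility cutoff.

    Substitutions scoring strictly below ``threshold`` are considered
    evolutionarily implausible and are removed by the matrix filter in
    post-processing.  Any PAM/BLOSUM table in NCBI-style whitespace-delimited
    layout can be loaded with :meth:`from_file`.
    """

    name: str
    scores: dict[tuple[str, str], float]
    threshold: float = -4.0
    alphabet: str = field(default=AA_ALPHABET)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None,
                  threshold: float = -4.0) -> "SubstitutionMatrix":
        path = Path(path)
        rows: list[list[str]] = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
        if not rows:
            raise ValueError(f"empty matrix file: {path}")
        header = rows[0]
        scores: dict[tuple[str, str], float] = {}
        seen: list[str] = []
        for row in rows[1:]:
            a, values = row[0], row[1:]
            if len(values) != len(header):
                raise ValueError(f"ragged matrix row for {a!r} in {path}")
            seen.append(a)
            for b, v in zip(header, values):
                scores[(a, b)] = float(v)
        if sorted(seen) != sorted(header):
            raise ValueError(f"matrix rows and columns disagree in {path}")
        alphabet = "".join(sorted(set(header) & set(AA_ALPHABET)))
        return cls(name=name or path.stem.upper(), scores=scores,
                   threshold=threshold, alphabet=alphabet)

    def score(self, wild: str, mutant: str) -> float:
        w, m = wild.upper(), mutant.upper()
        if (w, m) not in self.scores:
            raise KeyError(f"residue pair ({wild!r}, {mutant!r}) not in "
                           f"matrix {self.name}")
        return self.scores[(w, m)]

    def is_plausible(self, wild: str, mutant: str) -> bool:
        return self.score(wild, mutant) >= self.threshold


def matrix_score(matrix: SubstitutionMatrix, wild: str, mutant: str) -> float:
    """Pure lookup of the matrix entry for (wild, mutant)."""
    return matrix.score(wild, mutant)


def load_default_matrix(threshold: float = -4.0) -> SubstitutionMatrix:
    """Load the PAM-family matrix bundled with the package (PAM250)."""
    ref = resources.files("varminer.data") / "pam250.txt"
    with resources.as_file(ref) as path:
        return SubstitutionMatrix.from_file(path, name="PAM250",
                                            threshold=threshold)
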