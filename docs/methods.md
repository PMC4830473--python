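# Methods

This note records how `varminer` models variant mentions, which knobs
matter, what the synthetic generator does and does not emulate, and where
the genuinely open design choices were decided.

## The normalization model

A variant mention is reduced to a `NormalizedVariant`: sequence level
(protein `p`, coding DNA `c`, RNA `r`), kind (SUB, DEL, INS, INDEL, DUP,
FS, SNP), wild-type code, integer position, mutant code, and optionally a
dbSNP rsID. Substitutions require all three of wild/position/mutant; a SNP
identified only by rsID may leave them empty. Positions may be negative:
in forms like `Arg-23Thr` the minus denotes a location (an upstream
position under the default reading). The canonical key
`level|kind|wild|position|mutant[|rs_id]` is a lossless serialization and
is the identity used everywhere downstream — by the ensembles, the scorer
and the answer-set dialect. Levels are never merged: a DNA-level and a
protein-level description of the same biological event are distinct
records, because a corpus may legitimately annotate both.

Residue tokens are accepted as one-letter codes, three-letter codes and
full names (including the two-word acids, "aspartic acid" / "glutamic
acid", and the -ate synonyms). Selenocysteine and pyrrolysine are excluded
from the default alphabet: they do not occur in PAM-family matrices and
effectively never in mutation mentions, and excluding `U` as a residue
avoids clashing with uracil and with platform names like U133A. Codons are
translated under the standard genetic code with `U` folded to `T`; stop
codons yield `*`.

## Mention detection

Detection is deliberately rule-based: an ordered catalogue of named
regular-expression patterns shipped as a YAML resource
(`varminer/data/patterns.yaml`) and replaceable by the user. Each pattern
carries a form category and a parsing strategy. Notable decisions:

* **Overlap resolution.** All candidate matches are collected; the longest
  span wins, catalogue order breaks ties, and surviving mentions are
  non-overlapping and sorted by offset (0-based, half-open). Longest-match
  is what makes "G→A polymorphism at nucleotide 5557" beat its own
  position-less prefix.
* **Codon-indexed changes.** In "A to G transition at codon 557
  (AAG→GAG)" the index 557 is an amino-acid position, so the parser
  translates the two codons and emits `p|SUB|K|557|E`. Binding the bases
  to the index (A557G) is a known failure mode of extraction tools and is
  structurally impossible here: a base change whose position is a codon
  index and which lacks explicit codons is flagged non-informative.
* **Position attachment is strictly local.** A base change only receives a
  position from an immediately following "at nucleotide/position N". In
  "a C-to-G transition was identified at nucleotide 857 …" the intervening
  words break the attachment and the mention stays non-informative. This
  conservative choice trades a little recall for precision and matches how
  curated gold standards treat such sentences.
* **Compact wNm (`T790M`)** requires letter-digits-letter with no internal
  spaces or symbols, at the protein level. One-letter codes that are also
  bases (A, C, G, T) are read as residues in this form; nucleotide-level
  readings require an explicit arrow or level prefix. Forms with internal
  hyphens are handled by their own patterns: `X-N-Y` reads the hyphens as
  separators (position +N), `X-NY` reads the minus as part of the location
  (−N by default; a plain-position reading is a config switch,
  `minus_is_location=False`, since the upstream convention is not
  universal).
* **Arrow glyphs.** Full-text extraction mangles arrows; the catalogue
  accepts `>`, `->`, `→`, `⇒`, `=>` and the en-dash/`≥` artefacts
  (`–≥`) seen in real articles.
* **Deletions, insertions and frameshifts** are detected only from
  explicit keyword forms (`del`, `ins`, `fs`, "frameshift at codon N").
  Substitutions dominate real corpora by an order of magnitude, so depth
  here was not a priority; the data model carries the kinds regardless.

Mentions that parse incompletely (no position, no mutant, untranslatable
codon) are returned with the non-informative marker rather than dropped,
so the post-processing stage can log their removal explicitly.

## Post-processing

Corrections run before filters, so that corrected forms — not raw ones —
are what the filters judge; the correction rules can recover true
positives, which is why this order was chosen.

1. **Lexicon filter.** Surfaces matching cell-line, gene-symbol or
   platform-name lexicons (case-insensitive, whitespace-normalized) are
   removed, as are matches of productive decoy patterns. The bundled seed
   lexicons contain the classic mutation-like offenders (T47D, U133A, …)
   and are meant to be extended from files (one entry per line, `#`
   comments); figure labels are a context-sensitive pattern — `S13A` is
   removed after "Supplementary Figure" but kept elsewhere, where it may
   be a genuine Ser13Ala.
2. **Non-informative filter.** Mentions whose normalization is the
   non-informative marker are removed.
3. **Substitution-matrix filter.** Protein substitutions scoring strictly
   below a cutoff in an amino-acid log-odds matrix are removed. The
   bundled matrix is PAM250 in NCBI-style whitespace layout; any PAM or
   BLOSUM file in that layout can be substituted by path. The default
   cutoff is −4: conservative and moderately radical changes (P↔A +1,
   D↔N +2, K↔E 0, M↔R 0, T↔M −1) pass, while extreme pairs (W↔G −7,
   W↔C −8) are filtered. Stop-gain records bypass the rule (`*` is not a
   matrix residue), and the rule applies to protein-level records only —
   nucleotide changes carry no substitution-plausibility signal.
4. **Synonymous filter.** Substitutions with wild = mutant (`L367L`) are
   removed.
5. **Imbalanced-form correction.** A substitution whose surface has
   internal whitespace (a wild-type token glued to a number, "V 1691G")
   and which overlaps an explicit compact change in the text
   ("1691G > A") is re-anchored to the explicit change and re-normalized
   at the DNA level.
6. **Special-symbol correction.** Hyphen/minus forms are re-parsed under
   the grammar above; answer-set rows from external tools get the same
   treatment from their recorded surfaces.
7. **"for"-preposition correction.** In "substitution of X for Y", Y is
   the wild type and X the mutant; mentions parsed the other way around
   are flipped.

Every mention receives exactly one terminal outcome (`removed`,
`modified`, or `kept`) with the responsible rule, giving the conservation
law `|input| = |survivors| + |removed|` and making the module idempotent.
Each rule is independently switchable in `PostProcessConfig`.

## Ensembles and evaluation

Simple merging is the per-document union of canonical keys; majority
voting keeps keys present in at least `quorum` input sets (default 2,
two-of-three). Presence is counted once per input system regardless of
mention multiplicity; merged multiplicity is the maximum over contributing
inputs (union semantics — the combiners must not inflate mention counts).
Documents missing from an input count as empty for it. Quorum 1 equals
simple merging by construction.

Scoring pools TP/FP/FN over all documents before computing ratios
(micro-averaging), yielding one corpus-level P/R/F1 per metric mode. In
extracted-mentions mode the per-key matched count is
`min(pred multiplicity, gold multiplicity)`; normalized-mutations mode is
set intersection; document-retrieval mode compares per-document emptiness
only. Zero-denominator convention: a ratio with an empty denominator is
1.0 when the opposing side is also empty and 0.0 otherwise, so a
perfectly-empty corpus scores 1.0; F1 is 0 when P + R = 0.

## Synthetic corpora

`generate_corpus` emulates the statistical shape of variant-bearing
full-text passages: 1–3 variants per document realized in a weighted mix
of surface forms (compact wNm 0.45, three-letter 0.20, natural language
0.15, nucleotide change 0.10, codon change 0.05, rsID 0.05 — compact wNm
dominating as it does in real full text), Poisson-distributed decoys drawn
from the bundled lexicons plus figure labels and chemical formulae, a 10%
chance a variant is mentioned twice, residues uniform over the 20-letter
alphabet, positions uniform on 1–2000. Substitution pairs are sampled from
those passing the plausibility cutoff and realized surfaces are rejected
if they collide with a lexicon entry, so the generator's gold is exactly
recoverable; optional synonymous/implausible injection rates (default 0)
add non-gold realizations to exercise filters 3–4. Generation is a pure
function of the seed; equal specs give byte-identical corpora.

What the generator does **not** emulate: discourse structure, full-text
length (documents are a handful of sentences), novel decoy families
outside the bundled lexicons, typos, and gold-standard disagreement
between curators. Perfect scores on synthetic corpora therefore
demonstrate internal consistency of the pipeline over the closed form
catalogue — not expected performance on arbitrary literature, where
unseen surface forms and unlisted decoys will cost recall and precision.

The curated `worked_examples()` complement the generator: verbatim
sentences from published articles (keyed by PMID) that are documented hard
cases — mixed DNA/protein levels in one sentence, *for*-preposition
binding, codon-index arithmetic — plus short fragments for the three
correction rules, each paired with its known-correct gold annotation.

## Numerical and degenerate-input choices

* Matrix files must be square with identical row/column alphabets;
  asymmetric or ragged files are rejected at load time, as are missing
  lexicon resources (never silently skipped).
* Extraction of an empty document is an empty list; an empty answer set
  writes a header-only TSV.
* Duplicate (document, variant) rows on read are merged with summed
  multiplicity and a recorded warning; malformed rows fail with the row
  number.
* The unified dialect cannot represent a document with zero variants, so
  answer-set equality ignores variant-less documents.
* Ensemble inputs: an empty input list (merging) and a quorum below 1 or
  above the number of inputs (voting) are errors.

## Known limitations

* The extractor is pattern-based by design; natural-language coverage is
  the enumerated grammar, not a statistical model, and will miss creative
  phrasings.
* dbSNP mentions are kept as rsID records and not expanded to wNm form
  (that would require a local copy of dbSNP).
* No verification against reference sequences (no check that position 790
  of a given protein actually is threonine) and no genome-coordinate
  liftover.
* The bundled lexicons are seeds, not catalogues; production use should
  plug in full HUGO and cell-line lists.
* The minus-as-location sign convention for `X-NY` forms is genuinely
  ambiguous in the wild; both readings are implemented and the default
  (negative position) is a convention, not a fact about the texts.
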