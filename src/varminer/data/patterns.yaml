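# Ordered pattern catalogue for variant-mention detection.
#
# Each entry has:
#   name    - unique pattern identifier
#   form    - surface-form category assigned to matches
#   parser  - parsing strategy (dispatched in mention_extraction)
#   pattern - regular expression; placeholder tokens {AA1} {AA3} {AANY}
#             {BASE} {ARROW} {TO} are expanded at load time
#   level   - optional sequence level override for the parser
#
# Order defines priority: when two candidate matches of equal length overlap,
# the earlier pattern wins.  Longer matches always beat shorter ones.
patterns:

  # "A to G transition at codon 557 (AAG->GAG)": the index is a codon
  # (amino-acid) position, so the change is resolved by translating the
  # wild-type and mutant codons, never by binding the bases to the index.
  - name: codon_change_codons
    form: codon_change
    parser: codon_pair
    pattern: '{BASE}{TO}{BASE}\s+(?:transition|transversion|substitution|change|mutation)\s+at\s+codon\s+(?P<pos>\d+)\s*\(\s*(?P<wcodon>[ACGTU]{3})\s*{ARROW}\s*(?P<mcodon>[ACGTU]{3})\s*\)'

  # Same construction without the explicit codons: the bases are nucleotide
  # symbols but the position is a codon index, so no wNm form is derivable.
  - name: codon_change_bases_only
    form: codon_change
    parser: non_informative
    pattern: '{BASE}{TO}{BASE}\s+(?:transition|transversion|substitution|change|mutation)\s+at\s+codon\s+(?P<pos>\d+)'

  # "G->A polymorphism at nucleotide 5557"
  - name: nucleotide_change_nl
    form: nucleotide_change
    parser: dna_sub
    level: c
    pattern: '(?P<w>{BASE}){TO}(?P<m>{BASE})\s+(?:transition|transversion|polymorphism|substitution|change|mutation)\s+at\s+(?:nucleotide|nt\.?|position)\s+(?P<pos>\d+)'

  # Base change with no position attached ("C-to-G transition was
  # identified..."): detected but not convertible to wNm form.
  - name: base_change_no_position
    form: nucleotide_change
    parser: non_informative
    pattern: '(?P<w>{BASE}){TO}(?P<m>{BASE})\s+(?:transition|transversion|polymorphism)'

  # HGVS-style coding-DNA / RNA substitutions: "c.5557G>A", "r.76A>C"
  - name: hgvs_dna
    form: nucleotide_change
    parser: dna_sub_posfirst
    level: c
    pattern: '\bc\.\s*(?P<pos>-?\d+)\s*(?P<w>{BASE})\s*{ARROW}\s*(?P<m>{BASE})'
  - name: hgvs_rna
    form: nucleotide_change
    parser: dna_sub_posfirst
    level: r
    pattern: '\br\.\s*(?P<pos>-?\d+)\s*(?P<w>{BASE})\s*{ARROW}\s*(?P<m>{BASE})'

  # Bare compact nucleotide change: "1691G > A"
  - name: nucleotide_change_compact
    form: nucleotide_change
    parser: dna_sub_posfirst
    level: c
    pattern: '\b(?P<pos>\d+)\s*(?P<w>{BASE})\s*{ARROW}\s*(?P<m>{BASE})\b'

  # "substitution of alanine for proline at amino acid 286":
  # with the preposition "for", the SECOND residue is the wild type.
  - name: natural_sub_for
    form: natural_language
    parser: protein_sub_nl
    pattern: '[Ss]ubstitutions?\s+of\s+(?:an?\s+)?(?P<m>{AANY})\s+for\s+(?:an?\s+)?(?P<w>{AANY})(?:\s+at\s+(?:amino\s+acid|position|residue|codon)\s+(?P<pos>\d+))?'

  # "substitution of aspartic acid by asparagine at position 1853"
  - name: natural_sub_by
    form: natural_language
    parser: protein_sub_nl
    pattern: '[Ss]ubstitutions?\s+of\s+(?:an?\s+)?(?P<w>{AANY})\s+(?:by|with)\s+(?:an?\s+)?(?P<m>{AANY})(?:\s+at\s+(?:amino\s+acid|position|residue|codon)\s+(?P<pos>\d+))?'

  # "replacement of lysine by glutamic acid [at codon 557]"
  - name: natural_replacement
    form: natural_language
    parser: protein_sub_nl
    pattern: '[Rr]eplacements?\s+of\s+(?:an?\s+)?(?P<w>{AANY})\s+(?:by|with)\s+(?:an?\s+)?(?P<m>{AANY})(?:\s+at\s+(?:amino\s+acid|position|residue|codon)\s+(?P<pos>\d+))?'

  # "threonine 790 substituted with methionine"
  - name: natural_position_first
    form: natural_language
    parser: protein_sub_nl
    pattern: '(?P<w>{AANY})[\s-]+(?P<pos>\d+)\s+(?:is\s+|was\s+)?(?:substituted|replaced)\s+(?:with|by)\s+(?:an?\s+)?(?P<m>{AANY})'

  # "valine 600 is mutated": a variant is asserted but the mutant residue
  # is unrecoverable.
  - name: natural_non_informative
    form: natural_language
    parser: non_informative
    pattern: '(?P<w>{AANY})\s+(?P<pos>\d+)\s+(?:is|was)\s+(?:mutated|altered|changed)\b'

  # "Arg-23-Thr" / "A-23-T": the hyphens are separators, position is +N.
  - name: hyphen_separated_three
    form: wnm_long
    parser: wnm
    pattern: '\b(?P<w>{AA3})[-–−](?P<pos>\d+)[-–−](?P<m>{AA3})\b'
  - name: hyphen_separated_one
    form: wnm_short
    parser: wnm
    pattern: '\b(?P<w>{AA1})[-–−](?P<pos>\d+)[-–−](?P<m>{AA1})\b'

  # "Arg-23Thr" / "A-23T": the minus denotes location (upstream position
  # by default; plain position when minus_is_location is disabled).
  - name: minus_location_three
    form: wnm_long
    parser: minus_location
    pattern: '\b(?P<w>{AA3})[-–−](?P<pos>\d+)(?P<m>{AA3})\b'
  - name: minus_location_one
    form: wnm_short
    parser: minus_location
    pattern: '\b(?P<w>{AA1})[-–−](?P<pos>\d+)(?P<m>{AA1})\b'

  # "Thr790Met"
  - name: wnm_long
    form: wnm_long
    parser: wnm
    pattern: '\b(?P<w>{AA3})(?P<pos>\d+)(?P<m>{AA3})\b'

  # "T790M" - no internal whitespace or symbols allowed.
  - name: wnm_short
    form: wnm_short
    parser: wnm
    pattern: '\b(?P<w>{AA1})(?P<pos>\d+)(?P<m>{AA1})\b'

  # "rs121434569"
  - name: dbsnp_id
    form: dbsnp_id
    parser: dbsnp
    pattern: '\brs(?P<num>\d+)\b'

  # Explicit keyword-anchored deletions / insertions / frameshifts.
  - name: protein_deletion
    form: deletion
    parser: protein_del
    pattern: '\b(?P<w>{AA3}|{AA1})(?P<pos>\d+)del\b'
  - name: dna_deletion
    form: deletion
    parser: dna_del
    pattern: '\bc\.\s*(?P<pos>\d+)del(?P<w>{BASE})?\b'
  - name: dna_insertion
    form: insertion
    parser: dna_ins
    pattern: '\bc\.\s*(?P<pos>\d+)(?:_\d+)?ins(?:[ACGT]+)?\b'
  - name: protein_frameshift
    form: frameshift
    parser: protein_fs
    pattern: '\b(?P<w>{AA3}|{AA1})(?P<pos>\d+)fs\b'
  - name: frameshift_nl
    form: frameshift
    parser: fs_nl
    pattern: '[Ff]rameshift\s+(?:mutation\s+)?at\s+(?:codon|position)\s+(?P<pos>\d+)'
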