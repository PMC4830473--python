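# varminer

Rule-based extraction, normalization, post-processing, ensembling and
evaluation of genomic **variant mentions** in biomedical text.

Published articles describe the same point mutation in many surface forms —
`T790M`, `Thr790Met`, "threonine 790 substituted with methionine",
`c.5557G>A`, "A to G transition at codon 557 (AAG→GAG)", `rs121434569` —
and full text is littered with decoys that look exactly like mutations:
cell-line names (`T47D`), microarray platforms (`U133A`) and
supplementary-figure labels (`Figure S13A`). `varminer` is a toolkit for
text-mining pipelines and corpus curators that turns raw text into
normalized variant records, cleans up the systematic errors extraction
tools make, combines several tools' outputs, and scores predictions against
a gold standard.

## The model

Every mention is normalized to the **wNm convention**: wild-type residue
*w*, sequence position *N*, mutant residue *m*, qualified by sequence level
(`p` protein / `c` coding DNA / `r` RNA) and variant kind (SUB, DEL, INS,
FS, SNP, ...). The canonical serialization is pipe-delimited, e.g.
`p|SUB|T|790|M`; dbSNP mentions are kept as SNP records keyed by rsID.
Mentions that assert a variant without recoverable *w*, *N* and *m*
("valine 600 is mutated") are flagged non-informative.

Around the extractor sit three further stages:

* **Post-processing** — seven rules, corrections before filters:
  re-anchoring of imbalanced wild-type tokens next to explicit changes
  ("V 1691G" beside "1691G > A" → `c|SUB|G|1691|A`), hyphen-vs-minus
  disambiguation (`Arg-23-Thr` is position 23; in `Arg-23Thr` the minus
  denotes location), inversion of the preposition *for* ("substitution of X
  for Y" makes Y the wild type); then removal of lexicon decoys,
  non-informative mentions, evolutionarily implausible substitutions
  (PAM-matrix score below a cutoff) and synonymous changes (`L367L`).
* **Ensembles** — *simple merging* (per-document union over input systems)
  and *majority voting* (keep variants found by ≥ quorum systems,
  default 2).
* **Evaluation** — micro-averaged precision / recall / F1 under three
  modes: *extracted mentions* (every occurrence counts), *normalized
  mutations* (one per variant per document) and *document retrieval*
  (binary per document).

## Worked example

```python
from varminer import Document, MentionExtractor, PostProcessor

doc = Document(
    doc_id="PMID17517479",
    text=("Fifteen patients were heterozygous for the G–≥A polymorphism at "
          "nucleotide 5557, which causes substitution of asparagine for "
          "aspartic acid at position 1853 of the ATM protein."),
)
extractor = MentionExtractor()
processor = PostProcessor()
survivors, log = processor.process_mentions(doc, extractor.extract(doc))
for m in survivors:
    print(f"{m.surface!r} -> {m.normalized}")
```

prints

```
'G–≥A polymorphism at nucleotide 5557' -> c|SUB|G|5557|A
'substitution of asparagine for aspartic acid at position 1853' -> p|SUB|D|1853|N
```

— the same sentence yields both the coding-DNA change (G→A at nucleotide
5557) and the protein change it causes (aspartic acid → asparagine at
residue 1853, the *for*-preposition binding the second residue as wild
type). Scoring the bundled curated examples end to end
(`varminer.worked_examples()`) gives

```
P=1.000 R=1.000 F1=1.000 (TP=8, FP=0, FN=0)
```

## Command line

```bash
varminer simulate --seed 3 --n-docs 100 --out corpus/     # synthetic corpus + gold
varminer extract corpus/documents.jsonl --postprocess -o pred.tsv
varminer evaluate pred.tsv corpus/gold.tsv --metric normalized --json
varminer merge a.tsv b.tsv c.tsv -o merged.tsv
varminer vote a.tsv b.tsv c.tsv --quorum 2 -o voted.tsv
varminer postprocess raw.tsv --documents corpus/documents.jsonl -o clean.tsv
```

Answer sets travel in a unified TSV dialect (`doc_id, level, kind, wild,
position, mutant, rs_id, multiplicity, surfaces, source`) written
deterministically so equal sets are byte-identical on disk.

## Layout

| module | contents |
| --- | --- |
| `varminer.nomenclature` | residue/codon tables, `NormalizedVariant`, canonical keys, substitution matrices |
| `varminer.mention_extraction` | pattern-catalogue detector and parser (`data/patterns.yaml`, user-extendable) |
| `varminer.postprocessing` | the seven rules, lexicons, outcome log |
| `varminer.ensemble` | simple merging and majority voting |
| `varminer.evaluation` | the three metric modes and TP/FP/FN diffing |
| `varminer.corpus_io` | documents and the unified answer-set dialect |
| `varminer.synthetic` | seeded corpus generator and curated worked examples |
| `varminer.cli` | the `varminer` command |

See `docs/methods.md` for the underlying modelling choices and known
limitations.
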