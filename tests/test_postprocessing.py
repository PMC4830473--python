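"""The seven post-processing rules: four filters, three corrections.

Filters must only ever remove (survivors are a subset of the input) and the
corrections must only modify in place; together with the outcome log this
gives the conservation law len(input) == len(survivors) + len(removed).
"""

import pytest

from varminer import (
    AnswerSet,
    Document,
    MentionExtractor,
    PostProcessConfig,
    PostProcessor,
    parse_key,
)
from varminer.mention_extraction import ParsedChange, VariantMention
from varminer.nomenclature import Kind, Level
from varminer.postprocessing import Action, Rule, filter_mentions
from tests.conftest import run_pipeline


def mention_for(text: str, surface: str, parsed=None, form="wnm_short"):
    """Build an external-tool-style mention located in ``text``."""
    start = text.find(surface)
    assert start >= 0
    return VariantMention(doc_id="d", start=start, end=start + len(surface),
                          surface=surface, form=form, pattern="external",
                          parsed=parsed)


def extract_all(text: str):
    return MentionExtractor().extract(Document(doc_id="d", text=text))


class TestFilters:
    def test_lexicon_filter_removes_decoys(self, processor):
        text = "Samples: T47D, U133A and T790M were listed."
        mentions = [
            mention_for(text, "T47D",
                        ParsedChange(Level.PROTEIN, Kind.SUB, "T", 47, "D")),
            mention_for(text, "U133A"),
            mention_for(text, "T790M",
                        ParsedChange(Level.PROTEIN, Kind.SUB, "T", 790, "M")),
        ]
        survivors, outcomes = processor.filter_mentions(mentions, text=text)
        assert [m.surface for m in survivors] == ["T790M"]
        removed = {o.before.surface: o.rule_id for o in outcomes
                   if o.action is Action.REMOVED}
        assert removed == {"T47D": Rule.LEXICON, "U133A": Rule.LEXICON}

    def test_figure_label_decoy_requires_context(self, processor):
        text = "See Supplementary Figure S13A for details."
        [mention] = [m for m in extract_all(text) if m.surface == "S13A"]
        survivors, _ = processor.filter_mentions([mention], text=text)
        assert survivors == []
        # without figure context the same surface is a plausible Ser13Ala
        text2 = "The S13A mutant lost activity."
        [mention2] = [m for m in extract_all(text2) if m.surface == "S13A"]
        survivors2, _ = processor.filter_mentions([mention2], text=text2)
        assert [m.surface for m in survivors2] == ["S13A"]

    def test_non_informative_filter(self, processor):
        text = "In this tumor, valine 600 is mutated."
        mentions = extract_all(text)
        assert mentions and all(m.normalized is None for m in mentions)
        survivors, outcomes = processor.filter_mentions(mentions, text=text)
        assert survivors == []
        assert all(o.rule_id is Rule.NON_INFORMATIVE for o in outcomes)

    def test_synonymous_filter(self, processor):
        [mention] = extract_all("carrying the L367L change")
        assert mention.normalized.position == 367
        survivors, outcomes = processor.filter_mentions([mention])
        assert survivors == []
        assert outcomes[0].rule_id is Rule.SYNONYMOUS

    def test_matrix_filter_removes_implausible_substitutions(self, processor):
        [w_g] = extract_all("the W123G mutation")  # PAM250 score -7
        [t_m] = extract_all("the T790M mutation")  # PAM250 score -1
        survivors, outcomes = processor.filter_mentions([w_g, t_m])
        assert [m.surface for m in survivors] == ["T790M"]
        assert outcomes[0].rule_id is Rule.SUBSTITUTION_MATRIX

    def test_disabled_rules_are_identity(self, lexicons, matrix):
        config = PostProcessConfig(lexicon=False, non_informative=False,
                                   substitution_matrix=False,
                                   synonymous=False)
        text = "T47D and L367L and valine 600 is mutated and W123G."
        mentions = extract_all(text)
        survivors, outcomes = filter_mentions(mentions, lexicons, matrix,
                                              config, text=text)
        assert survivors == mentions
        assert all(o.action is Action.KEPT for o in outcomes)

    def test_conservation_law(self, processor):
        text = ("The T790M and L367L and W123G variants plus T47D cells "
                "and valine 600 is mutated.")
        mentions = extract_all(text)
        survivors, outcomes = processor.filter_mentions(mentions, text=text)
        removed = [o for o in outcomes if o.action is Action.REMOVED]
        assert len(mentions) == len(survivors) + len(removed)
        assert set(survivors) <= set(mentions)


class TestCorrections:
    def test_rule5_reanchors_imbalanced_wild_type(self, processor):
        text = ("The thrombosis-associated factor V 1691G > A variant was "
                "genotyped in all cases.")
        spurious = mention_for(
            text, "V 1691G",
            ParsedChange(Level.PROTEIN, Kind.SUB, "V", 1691, "G"))
        fixed, outcome = processor.correct_forms(text, spurious)
        assert outcome.rule_id is Rule.IMBALANCED_FORM
        assert outcome.action is Action.MODIFIED
        assert fixed.normalized.key == "c|SUB|G|1691|A"
        assert text[fixed.start:fixed.end] == fixed.surface

    def test_rule6_hyphen_is_separator(self, processor):
        text = "The Arg-23-Thr substitution was disruptive."
        wrong = mention_for(text, "Arg-23-Thr", None, form="wnm_long")
        fixed, outcome = processor.correct_forms(text, wrong)
        assert outcome.rule_id is Rule.SPECIAL_SYMBOL
        assert fixed.normalized.key == "p|SUB|R|23|T"

    def test_rule6_minus_denotes_location(self, processor):
        text = "The Arg-23Thr promoter variant was rare."
        wrong = mention_for(text, "Arg-23Thr", None, form="wnm_long")
        fixed, _ = processor.correct_forms(text, wrong)
        assert fixed.normalized.key == "p|SUB|R|-23|T"

    def test_rule6_minus_reading_switchable(self):
        proc = PostProcessor(config=PostProcessConfig(
            minus_is_location=False))
        text = "The Arg-23Thr promoter variant was rare."
        wrong = mention_for(text, "Arg-23Thr", None, form="wnm_long")
        fixed, _ = proc.correct_forms(text, wrong)
        assert fixed.normalized.key == "p|SUB|R|23|T"

    def test_rule7_for_binds_second_residue_as_wild_type(self, processor):
        text = "a substitution of arginine for methionine was found"
        surface = "substitution of arginine for methionine"
        # an external tool's wrong reading: first residue taken as wild type
        wrong = mention_for(text, surface,
                            ParsedChange(Level.PROTEIN, Kind.SUB, "R", None,
                                         "M"),
                            form="natural_language")
        fixed, outcome = processor.correct_forms(text, wrong)
        assert outcome.rule_id is Rule.FOR_PREPOSITION
        assert fixed.parsed.wild == "M" and fixed.parsed.mutant == "R"

    def test_uncorrectable_mention_kept(self, processor):
        text = "the T790M mutation"
        [mention] = extract_all(text)
        fixed, outcome = processor.correct_forms(text, mention)
        assert fixed == mention
        assert outcome.action is Action.KEPT


class TestAnswerSetPipeline:
    def test_decoy_only_answerset_is_emptied(self, processor):
        answers = AnswerSet()
        answers.add("doc1", parse_key("p|SUB|T|47|D"), surface="T47D")
        result, log = processor.process_answerset(answers)
        assert result.keys("doc1") == set()
        assert any(o.rule_id is Rule.LEXICON and o.action is Action.REMOVED
                   for o in log)

    def test_true_positives_untouched(self, processor, examples):
        docs, gold = examples
        result, _ = processor.process_answerset(
            gold, documents={d.doc_id: d for d in docs})
        assert result == gold

    def test_mixed_set_composition_of_rules(self, processor):
        """Rule 1 and rule 4 compose: their joint survivors equal the
        intersection of each rule's independent survivors."""
        text = "Both P286A and L367L were reported; T47D cells were used."
        mentions = extract_all(text)
        assert len(mentions) == 3
        full, _ = processor.filter_mentions(mentions, text=text)
        assert {m.normalized.key for m in full} == {"p|SUB|P|286|A"}

        only = {}
        for rule in ("lexicon", "synonymous"):
            config = PostProcessConfig(lexicon=False, non_informative=False,
                                       substitution_matrix=False,
                                       synonymous=False)
            setattr(config, rule, True)
            proc = PostProcessor(config=config)
            survivors, _ = proc.filter_mentions(mentions, text=text)
            only[rule] = {m.surface for m in survivors}
        assert only["lexicon"] & only["synonymous"] == \
            {m.surface for m in full}

    def test_idempotent(self, processor, examples):
        docs, _ = examples
        documents = {d.doc_id: d for d in docs}
        answers = run_pipeline(docs)
        once, _ = processor.process_answerset(answers, documents=documents)
        twice, _ = processor.process_answerset(once, documents=documents)
        assert once == twice

    def test_example_answers_survive_default_pipeline(self, examples):
        docs, gold = examples
        pred = run_pipeline(docs)
        for doc_id in gold.docs():
            assert gold.keys(doc_id) <= pred.keys(doc_id)
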