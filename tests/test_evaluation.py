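"""Precision/recall/F1 scoring under the three metric modes.

The unit of agreement differs per mode: every mention occurrence
(extracted_mentions), one per variant per document (normalized_mutations),
or one per document (document_retrieval).  Randomized corpora are checked
against a brute-force pairwise-matching oracle.
"""

import random

import pytest

from varminer import AnswerSet, Metric, diff, parse_key, score

KEYS = [f"p|SUB|T|{i}|M" for i in range(1, 9)]
A, B, C, D = KEYS[:4]


def make_set(doc_keys: dict[str, dict[str, int]]) -> AnswerSet:
    out = AnswerSet()
    for doc_id, keys in doc_keys.items():
        out.add_document(doc_id)
        for key, mult in keys.items():
            out.add(doc_id, parse_key(key), multiplicity=mult)
    return out


class TestScoreExamples:
    @pytest.mark.parametrize("metric", list(Metric))
    def test_perfect_agreement(self, metric):
        s = make_set({"d1": {A: 2, B: 1}, "d2": {C: 1}})
        r = score(s, s, metric)
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)
        assert r.fp == r.fn == 0

    def test_duplicate_mention_semantics(self):
        """A variant mentioned twice counts twice for mentions, once for
        normalized mutations."""
        gold = make_set({"d": {"p|SUB|T|790|M": 2}})
        pred = make_set({"d": {"p|SUB|T|790|M": 2}})
        assert score(pred, gold, Metric.EXTRACTED_MENTIONS).tp == 2
        assert score(pred, gold, Metric.NORMALIZED_MUTATIONS).tp == 1
        # extracting it only once leaves one mention unmatched
        pred_once = make_set({"d": {"p|SUB|T|790|M": 1}})
        r = score(pred_once, gold, Metric.EXTRACTED_MENTIONS)
        assert (r.tp, r.fp, r.fn) == (1, 0, 1)
        r2 = score(pred_once, gold, Metric.NORMALIZED_MUTATIONS)
        assert (r2.tp, r2.fp, r2.fn, r2.f1) == (1, 0, 0, 1.0)

    def test_two_thirds_example(self):
        gold = make_set({"d": {A: 1, B: 1, C: 1}})
        pred = make_set({"d": {A: 1, B: 1, D: 1}})
        r = score(pred, gold, Metric.NORMALIZED_MUTATIONS)
        assert (r.tp, r.fp, r.fn) == (2, 1, 1)
        assert r.precision == r.recall == r.f1 == pytest.approx(2 / 3)

    def test_document_retrieval_ignores_variant_identity(self):
        gold = make_set({"d1": {A: 1}, "d2": {}})
        pred_right = make_set({"d1": {A: 1}, "d2": {}})
        pred_wrong_variant = make_set({"d1": {D: 3}, "d2": {}})
        r1 = score(pred_right, gold, Metric.DOCUMENT_RETRIEVAL)
        r2 = score(pred_wrong_variant, gold, Metric.DOCUMENT_RETRIEVAL)
        assert r1.as_dict() == r2.as_dict()
        r3 = score(make_set({"d1": {}, "d2": {A: 1}}), gold,
                   Metric.DOCUMENT_RETRIEVAL)
        assert (r3.tp, r3.fp, r3.fn) == (0, 1, 1)

    def test_micro_averaging_pools_before_dividing(self):
        # one perfect doc and one all-wrong doc: micro P = 1/2, not 1/2-way
        # between per-doc precisions computed separately
        gold = make_set({"d1": {A: 1}, "d2": {B: 1}})
        pred = make_set({"d1": {A: 1}, "d2": {C: 1}})
        r = score(pred, gold, Metric.NORMALIZED_MUTATIONS)
        assert (r.tp, r.fp, r.fn) == (1, 1, 1)
        assert r.precision == 0.5

    def test_zero_denominator_conventions(self):
        empty = make_set({"d": {}})
        nonempty = make_set({"d": {A: 1}})
        perfect = score(empty, empty, Metric.NORMALIZED_MUTATIONS)
        assert (perfect.precision, perfect.recall, perfect.f1) == (1, 1, 1)
        miss = score(empty, nonempty, Metric.NORMALIZED_MUTATIONS)
        assert (miss.precision, miss.recall, miss.f1) == (0.0, 0.0, 0.0)
        spurious = score(nonempty, empty, Metric.NORMALIZED_MUTATIONS)
        assert (spurious.precision, spurious.recall) == (0.0, 0.0)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            score(make_set({}), make_set({}), "bogus")


class TestDiff:
    def test_identical_sets(self):
        s = make_set({"d": {A: 1, B: 1}})
        d = diff(s, s)
        assert d["d"] == {"tp": sorted([A, B]), "fp": [], "fn": []}

    def test_empty_prediction(self):
        gold = make_set({"d": {A: 1, B: 1}})
        d = diff(make_set({"d": {}}), gold)
        assert d["d"]["fn"] == sorted([A, B]) and d["d"]["tp"] == []

    def test_disjoint_sets(self):
        d = diff(make_set({"d": {B: 1}}), make_set({"d": {A: 1}}))
        assert d["d"] == {"tp": [], "fp": [B], "fn": [A]}

    def test_partition_is_exhaustive(self):
        rng = random.Random(5)
        for _ in range(50):
            pred = make_set({"d": {k: 1 for k in
                                   rng.sample(KEYS, rng.randint(0, 8))}})
            gold = make_set({"d": {k: 1 for k in
                                   rng.sample(KEYS, rng.randint(0, 8))}})
            d = diff(pred, gold)["d"]
            assert set(d["tp"]) | set(d["fp"]) == pred.keys("d")
            assert set(d["tp"]) | set(d["fn"]) == gold.keys("d")


def brute_force_counts(pred, gold, metric):
    """Enumerate matches pairwise per document, the slow way."""
    tp = fp = fn = 0
    for doc in sorted(set(pred.docs()) | set(gold.docs())):
        if metric is Metric.DOCUMENT_RETRIEVAL:
            p, g = bool(pred.keys(doc)), bool(gold.keys(doc))
            tp += p and g
            fp += p and not g
            fn += g and not p
            continue
        pred_units: list[str] = []
        gold_units: list[str] = []
        for key in pred.keys(doc):
            n = (pred.multiplicity(doc, key)
                 if metric is Metric.EXTRACTED_MENTIONS else 1)
            pred_units += [key] * n
        for key in gold.keys(doc):
            n = (gold.multiplicity(doc, key)
                 if metric is Metric.EXTRACTED_MENTIONS else 1)
            gold_units += [key] * n
        remaining = list(gold_units)
        for unit in pred_units:
            if unit in remaining:
                remaining.remove(unit)
                tp += 1
            else:
                fp += 1
        fn += len(remaining)
    return tp, fp, fn


class TestInvariants:
    def random_corpus(self, rng):
        return make_set({
            f"d{i}": {
                k: rng.randint(1, 3)
                for k in rng.sample(KEYS, rng.randint(0, len(KEYS)))
            }
            for i in range(rng.randint(1, 10))
        })

    def test_oracle_equivalence_on_random_corpora(self):
        rng = random.Random(2024)
        for _ in range(300):
            pred, gold = self.random_corpus(rng), self.random_corpus(rng)
            for metric in Metric:
                r = score(pred, gold, metric)
                assert (r.tp, r.fp, r.fn) == brute_force_counts(pred, gold,
                                                                metric)

    def test_count_conservation(self):
        rng = random.Random(77)
        for _ in range(100):
            pred, gold = self.random_corpus(rng), self.random_corpus(rng)
            r = score(pred, gold, Metric.EXTRACTED_MENTIONS)
            assert r.tp + r.fp == pred.n_mentions()
            assert r.tp + r.fn == gold.n_mentions()
            r = score(pred, gold, Metric.NORMALIZED_MUTATIONS)
            assert r.tp + r.fp == pred.n_variants()
            assert r.tp + r.fn == gold.n_variants()

    def test_f1_is_harmonic_mean(self):
        rng = random.Random(3)
        for _ in range(200):
            pred, gold = self.random_corpus(rng), self.random_corpus(rng)
            r = score(pred, gold, Metric.NORMALIZED_MUTATIONS)
            p, rc = r.precision, r.recall
            if p + rc > 0:
                assert r.f1 == pytest.approx(2 * p * rc / (p + rc))
                assert r.f1 <= min(1.0, 2 * min(p, rc))
            assert 0.0 <= r.f1 <= 1.0
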