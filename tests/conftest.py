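import pytest

from varminer import (
    AnswerSet,
    MentionExtractor,
    PostProcessor,
    load_default_lexicons,
    load_default_matrix,
    worked_examples,
)


@pytest.fixture(scope="session")
def extractor() -> MentionExtractor:
    return MentionExtractor()


@pytest.fixture(scope="session")
def matrix():
    return load_default_matrix()


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture()
def processor() -> PostProcessor:
    return PostProcessor()


@pytest.fixture(scope="session")
def examples():
    """Curated example documents and their gold annotations."""
    return worked_examples()


def run_pipeline(docs, extractor=None, processor=None) -> AnswerSet:
    """Extract + post-process a document list into an answer set."""
    extractor = extractor or MentionExtractor()
    processor = processor or PostProcessor()
    pred = AnswerSet()
    for doc in docs:
        survivors, _ = processor.process_mentions(doc, extractor.extract(doc))
        pred.add_document(doc.doc_id)
        for m in survivors:
            v = m.normalized
            if v is not None:
                pred.add(doc.doc_id, v, surface=m.surface)
    return pred
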