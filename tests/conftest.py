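import pytest

from clinsyn.corpus import Document, MentionAnnotation, Span, tokenize
from clinsyn.synthetic import GenConfig, generate


@pytest.fixture(scope="session")
def default_corpus():
    """The standard synthetic study corpus: 25 concepts x 3 lexically
    dissimilar forms, strong context cues, ~600 mentions."""
    config = GenConfig(seed=1)
    concepts, documents, mentions, admissions = generate(config)
    return {
        "config": config,
        "concepts": concepts,
        "documents": documents,
        "mentions": mentions,
        "admissions": admissions,
    }


@pytest.fixture(scope="session")
def default_sentences(default_corpus):
    return [s for d in default_corpus["documents"] for s in tokenize(d)]


@pytest.fixture
def toy_document():
    return Document(doc_id="d1", text="Pt has sepsis.\nNo CP today.")


@pytest.fixture
def toy_mentions():
    return [
        MentionAnnotation("m1", "d1", (Span(7, 13),), "sepsis", "C001", fold="all"),
        MentionAnnotation("m2", "d1", (Span(18, 20),), "CP", "C002", fold="all"),
    ]
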