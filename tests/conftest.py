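import pytest

from clinconcept import FixtureSpec, generate_synthetic_corpus, paper_fixture_backend
from clinconcept.backend import FixtureBackend


@pytest.fixture(scope="session")
def backend():
    """The paper-derived fixture knowledge base as an in-memory backend."""
    return paper_fixture_backend()


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus (seed 1, 3 docs x 5 concepts)."""
    return generate_synthetic_corpus(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_corpus_backend(default_corpus):
    return FixtureBackend(default_corpus.kb)
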