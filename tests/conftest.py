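import pytest

import biopax2gocam as bg
from biopax2gocam.fixtures import (
    FixtureSpec,
    make_crym_fixture,
    make_edge_case_suite,
    make_random_pathway_corpus,
)


@pytest.fixture(scope="session")
def crym_bytes() -> bytes:
    return make_crym_fixture()


@pytest.fixture(scope="session")
def crym_collection(crym_bytes):
    return bg.parse_biopax(crym_bytes)


@pytest.fixture()
def crym_result(crym_bytes):
    # fresh conversion per test: results are mutable
    return bg.convert_document(crym_bytes)


@pytest.fixture(scope="session")
def corpus_spec() -> FixtureSpec:
    return FixtureSpec(n_pathways=6, n_disease_pathways=1, n_drug_reactions=2, seed=11)


@pytest.fixture(scope="session")
def corpus(corpus_spec):
    return make_random_pathway_corpus(corpus_spec)


@pytest.fixture()
def corpus_result(corpus):
    document, _ledger = corpus
    return bg.convert_document(
        document, filter_config=bg.FilterConfig(disease_roots=["R-TST-DISEASE"])
    )


@pytest.fixture(scope="session")
def edge_suite():
    return make_edge_case_suite()
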