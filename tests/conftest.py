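import pytest

from elikb import load_ontology
from elikb.patient_matching import CriterionMatcher
from elikb.synthetic import GeneratorConfig, gen_criteria_corpus, template_lexicon


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture(scope="session")
def small_corpus():
    """150 generated criteria with gold mentions and relations."""
    return gen_criteria_corpus(GeneratorConfig(seed=3, n_criteria=150)).criteria


@pytest.fixture(scope="session")
def lexicon():
    return template_lexicon()


@pytest.fixture(scope="session")
def matcher():
    return CriterionMatcher()
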