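import pytest

from hedgescope.fixtures_synth import (SynthParams, sentence1_fixture,
                                       sentence2_fixture, synthetic_corpus)


@pytest.fixture(scope="session")
def s1():
    return sentence1_fixture().sentence


@pytest.fixture(scope="session")
def s2_good():
    return sentence2_fixture("corrected").sentence


@pytest.fixture(scope="session")
def s2_bad():
    return sentence2_fixture("parse_error").sentence


@pytest.fixture(scope="session")
def small_corpus():
    """A noise-free synthetic corpus at generator defaults (100 sentences)."""
    return synthetic_corpus(SynthParams(seed=11))
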