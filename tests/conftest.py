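import pytest

from tbiextract.lexicon import build_catalog, load_default_lexicons


@pytest.fixture(scope="session")
def lexicons():
    """Starter (target, modifier) lexicons shipped as package data."""
    return load_default_lexicons()


@pytest.fixture(scope="session")
def target_lexicon(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def modifier_lexicon(lexicons):
    return lexicons[1]


@pytest.fixture(scope="session")
def catalog(target_lexicon):
    return build_catalog(target_lexicon)
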