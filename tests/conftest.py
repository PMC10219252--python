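import pytest

from fdscreen import MatcherConfig, default_catalog, default_lexicon
from fdscreen.lexicon import Lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def matcher():
    return MatcherConfig()


@pytest.fixture()
def tiny_lexicon():
    """A small hand-built lexicon for targeted matcher tests."""
    lex = Lexicon(
        negation_cues=["no", "not", "without", "denies"],
        reset_tokens=["but", "however"],
        lemma_rules=[("omas", "oma")],
    )
    lex.add_term("angiokeratoma", "angiokeratoma", feature_id="angiokeratoma")
    lex.add_term("cornea", "cornea", feature_id="cornea_verticillata")
    lex.add_term(
        "cornea_verticillata", "cornea verticillata", feature_id="cornea_verticillata"
    )
    lex.add_term(
        "proteinuria", "proteinuria", synonyms=["protein in urine"],
        feature_id="proteinuria",
    )
    return lex
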