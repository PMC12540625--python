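import pytest

from spyquest import build_default_lexicon, default_schema, generate_room


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def lexicon(schema):
    return build_default_lexicon(schema)


@pytest.fixture(scope="session")
def room50(schema):
    return generate_room(schema, 50, seed=1)
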