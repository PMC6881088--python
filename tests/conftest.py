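import pytest

from radsite import build_fixture_lexicon, fixture_annotator


@pytest.fixture(scope="session")
def fixture_lexicon():
    return build_fixture_lexicon()


@pytest.fixture(scope="session")
def annotator():
    """Pipeline over the embedded lexicon (shared; treat as read-only)."""
    return fixture_annotator()
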