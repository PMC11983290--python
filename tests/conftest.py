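import datetime as dt

import pytest

from abc_autoscore import Note, default_pattern_config


@pytest.fixture(scope="session")
def pattern_config():
    return default_pattern_config()


@pytest.fixture(scope="session")
def matchers(pattern_config):
    """Compiled matchers keyed by item id."""
    return {m.item.item_id: m for m in pattern_config.compile()}


@pytest.fixture
def make_note():
    def _make(text, pid="p1", nid="n1", when=dt.datetime(2020, 6, 1, 9, 0)):
        return Note(pid, nid, when, "progress note", text)

    return _make
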