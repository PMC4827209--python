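import pytest

from algatf.rules import default_rules


@pytest.fixture(scope="session")
def ruleset():
    return default_rules()
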