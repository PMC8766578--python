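import pytest

from dietscape.classify import RuleSet


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet.default()
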