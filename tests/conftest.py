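import pytest

from odormine import toy_dataset


@pytest.fixture
def toy():
    return toy_dataset()
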