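import pytest

from hpcoil import load_reference


@pytest.fixture(scope="session")
def db():
    return load_reference()
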