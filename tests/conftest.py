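import pytest

from hrdscar.genome import load_genome


@pytest.fixture(scope="session")
def toy_genome():
    return load_genome("toy")


@pytest.fixture(scope="session")
def grch38_lite():
    return load_genome("GRCh38-lite")
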