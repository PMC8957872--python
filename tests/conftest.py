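import pytest

from quinonefold.topology import build_topology


@pytest.fixture(scope="session")
def uq2():
    return build_topology("UQ", 2)


@pytest.fixture(scope="session")
def mk2():
    return build_topology("MK", 2)
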