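import pytest

from cucirc.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_sim():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def paper_mix_sim():
    return make_fixture("paper_mix")


@pytest.fixture(scope="session")
def de_benchmark_sim():
    return make_fixture("de_benchmark")
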