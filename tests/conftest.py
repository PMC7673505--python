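import pytest

from seqdecide import init_params
from seqdecide.tasks.probreason import build_codebook


@pytest.fixture(scope="session")
def codebook():
    return build_codebook()


@pytest.fixture
def small_params():
    return init_params(6, 5, 6, seed=7)
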