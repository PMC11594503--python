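import pytest

from poregibbs import generate_core, template_library


@pytest.fixture(scope="session")
def templates():
    return template_library()


@pytest.fixture(scope="session")
def organic_rich_core(templates):
    core, truth = generate_core(templates["organic_rich_CLB_like"], seed=1)
    return core, truth


@pytest.fixture(scope="session")
def organic_poor_core(templates):
    core, truth = generate_core(templates["organic_poor_WOR_like"], seed=1)
    return core, truth
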