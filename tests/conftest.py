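import pytest

from ssir.datasets import load_fpr, load_toy_spec, make_toy_labeled


@pytest.fixture(scope="session")
def fpr():
    return load_fpr()


@pytest.fixture(scope="session")
def toy_spec():
    return load_toy_spec()


@pytest.fixture(scope="session")
def toy_lib():
    # a=15 known, b=5 of interest sublibrary of the 24-analogue toy space
    return make_toy_labeled(seed=3)
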