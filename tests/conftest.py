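import pytest

from ahprank import load_porphyrin_experiments, load_porphyrin_hierarchy


@pytest.fixture(scope="session")
def porphyrin_hierarchy():
    return load_porphyrin_hierarchy()


@pytest.fixture(scope="session")
def porphyrin_hierarchy_5():
    return load_porphyrin_hierarchy("5")


@pytest.fixture(scope="session")
def experiment_records():
    return load_porphyrin_experiments()
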