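import pytest

from enzapbpk import datasets


@pytest.fixture(scope="session")
def induction_table():
    return datasets.load_induction_table()


@pytest.fixture(scope="session")
def transwell_table():
    return datasets.load_transwell_table()


@pytest.fixture(scope="session")
def enzalutamide():
    return datasets.load_packaged_compound("enzalutamide")


@pytest.fixture(scope="session")
def m2():
    return datasets.load_packaged_compound("m2")


@pytest.fixture(scope="session")
def digoxin():
    return datasets.load_packaged_compound("digoxin")


@pytest.fixture(scope="session")
def default_system():
    return datasets.load_default_system()
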