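import pytest

from nitriso import io as nio


@pytest.fixture(scope="session")
def table2():
    return nio.load_table("no3_isotopes")


@pytest.fixture(scope="session")
def table3():
    return nio.load_table("reduced_n")


@pytest.fixture(scope="session")
def table6():
    return nio.load_table("triple_oxygen")


@pytest.fixture(scope="session")
def samples():
    return nio.study_samples()
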