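import numpy as np
import pytest

from p450select import table1_fixture

PAIR_34 = ("3'-OH-MF", "4'-OH-MF")
PAIR_35 = ("3'-OH-MF", "5-OH-MF")
PAIR_45 = ("4'-OH-MF", "5-OH-MF")


@pytest.fixture(scope="session")
def fixture_table():
    return table1_fixture()


@pytest.fixture(scope="session")
def bm3(fixture_table):
    return fixture_table.subset("BM3 M11")


@pytest.fixture(scope="session")
def cyp1a2(fixture_table):
    return fixture_table.subset("CYP1A2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
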