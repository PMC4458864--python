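import pytest

from mrpool.datasets import (
    load_fg_instruments,
    load_fg_table4,
    load_t2d_clusters,
    load_t2d_instruments,
    load_t2d_table1,
)


@pytest.fixture(scope="session")
def t2d_table():
    return load_t2d_table1()


@pytest.fixture(scope="session")
def fg_table():
    return load_fg_table4()


@pytest.fixture(scope="session")
def t2d_instruments():
    """The 26 screened T2D->CHD instruments."""
    return load_t2d_instruments(screened=True)


@pytest.fixture(scope="session")
def t2d_candidates():
    """All 37 T2D candidate instruments, pleiotropic ones included."""
    return load_t2d_instruments(screened=False)


@pytest.fixture(scope="session")
def fg_instruments():
    """The 24 screened FG->CHD instruments (mmol/l exposure scale)."""
    return load_fg_instruments(screened=True)


@pytest.fixture(scope="session")
def t2d_clusters():
    return load_t2d_clusters()
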