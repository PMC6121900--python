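import pytest

from ptmgrav import (
    classify_records,
    load_reference_sites,
    load_reference_table,
    select_candidates,
)


@pytest.fixture(scope="session")
def ftc_table():
    return load_reference_table("FTC-133")


@pytest.fixture(scope="session")
def mcf_table():
    return load_reference_table("MCF-7")


@pytest.fixture(scope="session")
def reference_sites():
    return load_reference_sites()


@pytest.fixture(scope="session")
def classified_sites(reference_sites):
    return classify_records(reference_sites)


@pytest.fixture(scope="session")
def reference_selection(ftc_table, mcf_table):
    return select_candidates(ftc_table, mcf_table)
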