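import pytest

from tp53proxy import (
    call_cohort,
    load_table1,
    synthetic_panel113,
    synthetic_sd1_validation40,
)

CGM097 = "NVP-CGM097"
CFC218 = "NVP-CFC218"


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture(scope="session")
def table1_calls(table1_records):
    return call_cohort(table1_records)


@pytest.fixture(scope="session")
def validation40():
    return synthetic_sd1_validation40()


@pytest.fixture(scope="session")
def panel113():
    return synthetic_panel113()
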