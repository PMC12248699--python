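import pytest

from int2grate_vhl import encoder, synthetic_cohort
from int2grate_vhl.gene_annotation import load_transcript_map
from int2grate_vhl.vef_engine import load_scenario_table


@pytest.fixture(scope="session")
def table():
    return load_scenario_table()


@pytest.fixture(scope="session")
def tmap():
    return load_transcript_map()


@pytest.fixture(scope="session")
def portal_encoded(table):
    rows = synthetic_cohort.fixture("portal_c340+578")
    df, _ = encoder.encode_table(rows, table)
    return df


@pytest.fixture(scope="session")
def patients_encoded(table):
    rows = synthetic_cohort.fixture("patients_21_23")
    df, _ = encoder.encode_table(rows, table)
    return df
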