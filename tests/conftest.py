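import numpy as np
import pytest

import fingercount as fc


@pytest.fixture(scope="session")
def finger_table():
    return fc.load_finger_table()


@pytest.fixture(scope="session")
def mfcc_table():
    return fc.load_mfcc_table()


@pytest.fixture(scope="session")
def trained_system():
    """One trained system (three RNNs + five datasets), shared across tests."""
    return fc.build_system(fc.ExperimentConfig(base_seed=0))


@pytest.fixture(scope="session")
def number_system(trained_system):
    """Trained system plus associative maps and a variant-5 classifier."""
    return fc.make_number_system(fc.ExperimentConfig(base_seed=0),
                                 system=trained_system)


@pytest.fixture(scope="session")
def normalized_tables(finger_table, mfcc_table):
    return (fc.normalize(finger_table.values).values,
            fc.normalize(mfcc_table.values).values)
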