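import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from btnscreen import io_

    return io_.load_reference_panel()


@pytest.fixture(scope="session")
def table1():
    from btnscreen import io_

    return io_.load_table1()


@pytest.fixture(scope="session")
def table1_seqs():
    from btnscreen import io_

    return io_.table1_sequences()


@pytest.fixture(scope="session")
def table1_clone_sets(table1, table1_seqs):
    from btnscreen import io_

    return io_.table1_clone_sets(table1, table1_seqs)


@pytest.fixture(scope="session")
def table1_genotypes():
    from btnscreen import io_

    return io_.table1_genotypes()


@pytest.fixture
def rng():
    return np.random.default_rng(20210311)
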