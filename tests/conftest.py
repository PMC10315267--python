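import numpy as np
import pytest

from zeitprot import load_table_fixture
from zeitprot.interactors import call_all_interactors, classify_timepoints


@pytest.fixture(scope="session")
def table1():
    return load_table_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_table_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_table_fixture("table3")


@pytest.fixture(scope="session")
def pooled_classification(table1, table2):
    """Pooled ZT5/ZT9 classification across the three clock baits."""
    return classify_timepoints(call_all_interactors(table1), call_all_interactors(table2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def cosine_trace(period_h=24.0, phase_h=4.0, amplitude=2.0, baseline=5.0, span_h=120.0, dt_h=1.0):
    """Convenience constructor for clean cosine traces."""
    from zeitprot.rhythm import LuminescenceTrace

    t = np.arange(0.0, span_h, dt_h)
    y = baseline + amplitude * np.cos(2 * np.pi * (t - phase_h) / period_h)
    return LuminescenceTrace(times=t, values=y)
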