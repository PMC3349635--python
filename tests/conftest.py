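import pytest

from allelosep.data_model import load_paper_fixture


@pytest.fixture(scope="session")
def table1_summaries():
    """Packaged mixed-culture group means (the index-table inputs)."""
    return load_paper_fixture("table1_means")


@pytest.fixture(scope="session")
def table3_rates():
    """Packaged TB/AE inhibitory rates per donor × trait."""
    return load_paper_fixture("table3_ir")
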