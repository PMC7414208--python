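import pytest

from watertaste import ContingencyTable2x2, paper_dataset, paper_fixture


@pytest.fixture(scope="session")
def paper_table() -> ContingencyTable2x2:
    """Overall arm-by-response counts of the published 278-participant study."""
    return ContingencyTable2x2(106, 33, 110, 29)


@pytest.fixture(scope="session")
def fixture_study():
    """Deterministic participant-level expansion of the study fixture."""
    return paper_dataset()


@pytest.fixture(scope="session")
def fixture():
    return paper_fixture()
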