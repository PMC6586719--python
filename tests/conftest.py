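import pytest

from crisprkit.simulate import table2_fixture


@pytest.fixture(scope="session")
def fixture_gene():
    """The printed target-region fixture: WT 47-mer, mutant alleles, and
    the synthetic gene model embedding the target in frame."""
    return table2_fixture()
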