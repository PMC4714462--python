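import pytest

from ervkit import discovery, simulate


@pytest.fixture(scope="session")
def provirus():
    return simulate.make_ancestral_provirus(seed=42)


@pytest.fixture(scope="session")
def consensus(provirus):
    return discovery.ConsensusModel(
        name=provirus.name,
        sequence=provirus.sequence,
        orfs=provirus.orfs,
        ltr=provirus.ltr5,
    )
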