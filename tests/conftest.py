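import pytest

from mitoblocks import pipeline, synth


@pytest.fixture(scope="session")
def two_inversion_case():
    """The canonical five-region two-inversion comparison (fixed seed)."""
    return synth.make_two_inversion_case(42)


@pytest.fixture(scope="session")
def two_inversion_report(two_inversion_case):
    anc, obs, _ = two_inversion_case
    return pipeline.compare_genomes(anc, obs)
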