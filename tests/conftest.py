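import pytest

from cishap import load_packaged_cohort
from cishap import synthetic_data as syn


@pytest.fixture(scope="session")
def packaged():
    """(cohort records, variant table) from the packaged study transcription."""
    return load_packaged_cohort()


@pytest.fixture(scope="session")
def cohort(packaged):
    return packaged[0]


@pytest.fixture(scope="session")
def table(packaged):
    return packaged[1]


@pytest.fixture(scope="session")
def small_scenario():
    """A small, fully informative synthetic scenario: every proband has a
    trio and error-free fragments."""
    cfg = syn.oca2_like(11, n_probands=30, trio_fraction=1.0, fragment_error=0.0,
                        fragment_depth=20)
    return cfg, syn.gen_cohort(cfg)


@pytest.fixture(scope="session")
def splice_training():
    cfg = syn.oca2_like(3, n_training_sites=400, n_decoys=400)
    return syn.gen_splice_training(cfg)
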