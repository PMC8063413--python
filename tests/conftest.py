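import numpy as np
import pytest

from mipepscan.synthio import SimConfig, simulate_transcriptome, simulate_ribopeptides


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def transcriptome(default_config):
    """One shared synthetic transcriptome with its planted-ORF truth table."""
    return simulate_transcriptome(default_config)


@pytest.fixture(scope="session")
def peptide_set(default_config, transcriptome):
    transcripts, truth = transcriptome
    return simulate_ribopeptides(default_config, truth, transcripts)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
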