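import numpy as np
import pytest

from specnoise import (
    CorpusConfig,
    JitterModel,
    NoiseConfig,
    Peptide,
    UnknownPeakModel,
    generate_corpus,
    predict_spectrum,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def peptide10():
    """Length-10 tryptic peptide with 10 distinct residues."""
    return Peptide("GASPVTLFNK")


@pytest.fixture
def clean_spectrum(peptide10):
    return predict_spectrum(peptide10)


@pytest.fixture(scope="session")
def clean_corpus():
    """Noise-free paired corpora: realified equals predicted."""
    config = CorpusConfig(n_spectra=30, seed=7)
    return generate_corpus(config)


@pytest.fixture(scope="session")
def noisy_corpus():
    """Full noise stack on a small corpus."""
    noise = NoiseConfig(
        jitter=JitterModel(method=2),
        missing_peaks=True,
        unknown=UnknownPeakModel(method="combined"),
        unknown_count=25,
        extra_ion_rate=0.2,
        seed=99,
    )
    config = CorpusConfig(n_spectra=40, seed=11, noise=noise)
    return generate_corpus(config)
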