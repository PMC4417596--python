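import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def noiseless_spectra():
    """Default noiseless 4-echo spectrum set with its generating truth."""
    from marrowlab.synthetic import SpectrumGenSpec, generate_spectrum
    return generate_spectrum(SpectrumGenSpec(pdff_true=0.32, snr=np.inf))


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_spectra):
    """Full fit chain on the default noiseless spectrum set."""
    from marrowlab.mrs import estimate_pdff
    spectra, truth = noiseless_spectra
    result, fits = estimate_pdff(spectra)
    return result, fits, truth
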