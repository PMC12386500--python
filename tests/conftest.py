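import numpy as np
import pytest

from neuroftir import pipeline, preprocess as pp, synth


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless dataset: exact Gaussian mixtures, default trends."""
    return synth.simulate_dataset(pipeline.fixture_config("clean", seed=0))


@pytest.fixture(scope="session")
def default_dataset():
    """Study-condition dataset: 7 DIV x 8 bio x 3 tech, default noise."""
    return synth.simulate_dataset(pipeline.fixture_config("default", seed=1))


@pytest.fixture(scope="session")
def default_regions(default_dataset):
    """Preprocessed (raw, derivative) spectra per region for the default dataset."""
    raw, deriv = {}, {}
    for region in pp.Region:
        r = pp.preprocess_pipeline(default_dataset, region)
        raw[region] = r
        deriv[region] = [pp.second_derivative(s) for s in r]
    return raw, deriv


@pytest.fixture(scope="session")
def clean_regions(clean_dataset):
    raw, deriv = {}, {}
    for region in pp.Region:
        r = pp.preprocess_pipeline(clean_dataset, region)
        raw[region] = r
        deriv[region] = [pp.second_derivative(s) for s in r]
    return raw, deriv


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def gaussian(nu, center, sigma, amp=1.0):
    return amp * np.exp(-((nu - center) ** 2) / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def single_band_spectrum():
    """A lone Gaussian band on a descending step-4 grid (no baseline/noise)."""
    nu = 1900.0 - 4.0 * np.arange(126)  # 1900..1400
    return synth.Spectrum(nu, gaussian(nu, 1650.0, 12.0, 0.8), {"sample_id": "s0"})
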