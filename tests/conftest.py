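import numpy as np
import pytest

from flourspec.spectra import SpectraSet
from flourspec.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng):
    """Tiny hand-built spectra set with a reference column."""
    wl = np.array([900.0, 1200.0, 1460.0, 1700.0])
    A = rng.uniform(0.1, 1.0, size=(6, 4))
    return SpectraSet(
        wavelengths_nm=wl,
        absorbance=A,
        sample_ids=[f"s{i}" for i in range(6)],
        reference=rng.uniform(18.0, 42.0, size=6),
        reference_label="SV",
    )


@pytest.fixture(scope="session")
def default_synthetic():
    """One seeded draw of the default (broad-band, SV-like) preset."""
    return generate(SyntheticConfig.preset("sv_like", n_samples=150, seed=11))


@pytest.fixture(scope="session")
def localized_synthetic():
    """One seeded draw of the narrow-band localization preset."""
    return generate(SyntheticConfig.preset("localized", n_samples=120, seed=5))


def standardized_xy(spectra):
    """Autoscaled matrix and target from a SpectraSet (population SD)."""
    from flourspec.spectra import fit_standardizer_arrays

    std = fit_standardizer_arrays(spectra.absorbance, spectra.reference)
    return std.transform(spectra.absorbance), std.transform_target(spectra.reference)
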