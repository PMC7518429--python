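import numpy as np
import pytest

from ramanmet import synthetic
from ramanmet.spectra import SpectraMatrix, Spectrum


@pytest.fixture(scope="session")
def raman_matrix():
    """5 groups x 10 spectra at 2% noise, seed 0 — the study-like conditions."""
    return synthetic.simulate_spectra_matrix(
        n_groups=5, n_per_group=10, lipid_fraction_by_group=(0.6, 0.5, 0.4, 0.3, 0.2),
        noise_sd=0.02, seed=0,
    )


@pytest.fixture(scope="session")
def srs_field():
    return synthetic.simulate_srs_field(n_cells=4, droplets_per_cell=3, image_size=256, seed=0)


@pytest.fixture(scope="session")
def expression():
    return synthetic.simulate_expression_matrix(seed=0)


@pytest.fixture
def gauss_spectrum():
    wn = np.arange(2800.0, 3051.0, 1.0)
    intens = 0.2 + np.exp(-0.5 * ((wn - 2900.0) / 10.0) ** 2)
    return Spectrum(wavenumbers=wn, intensities=intens, label="gauss")


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    return SpectraMatrix(
        features=[f"f{i}" for i in range(6)],
        samples=[f"s{j}" for j in range(4)],
        values=rng.uniform(0.5, 2.0, size=(6, 4)),
    )
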