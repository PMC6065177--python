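import numpy as np
import pytest

import phasorfold as pf


@pytest.fixture
def grid_nm():
    return np.arange(290.0, 401.0, 1.0)


@pytest.fixture
def gaussian_spectrum(grid_nm):
    """Gaussian band centered at 303 nm, sd 10 nm, on the 1-nm grid."""
    inten = np.exp(-0.5 * ((grid_nm - 303.0) / 10.0) ** 2)
    return pf.EmissionSpectrum(wavelengths_nm=grid_nm, intensities_au=inten)


@pytest.fixture
def chemical_config():
    """Noiseless two-state chemical titration, DeltaG0=5, m=4 (midpoint 1.25 M)."""
    return pf.two_state_chemical(
        5.0, 4.0, axis_values=np.arange(0.0, 3.01, 0.1), seed=11
    )


def pure_anchors(config):
    """CSM of the pure folded / unfolded basis spectra of a titration config."""
    vi = pf.center_of_spectral_mass(pf.pure_state_spectrum(config, 0))
    vf = pf.center_of_spectral_mass(pf.pure_state_spectrum(config, -1))
    return vi, vf


@pytest.fixture
def anchors():
    """Helper computing pure-state CSM anchors for a titration config."""
    return pure_anchors
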