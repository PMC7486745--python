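import numpy as np
import pytest

from spincascade import CascadeParams, species_spectrum, synth_timeseries
from spincascade.synthetic_data import default_xes_grid


@pytest.fixture(scope="session")
def xanes_truth() -> CascadeParams:
    """Cascade ground truth of the XANES kinetic experiment."""
    return CascadeParams(t0_ps=0.0, irf_fwhm_ps=0.14, tau1_ps=0.61,
                         tau3_ps=8.7, f_exc=0.3)


@pytest.fixture(scope="session")
def xes_truth() -> CascadeParams:
    """Cascade ground truth of the K-alpha emission kinetic experiment."""
    return CascadeParams(t0_ps=0.0, irf_fwhm_ps=0.15, tau1_ps=0.63,
                         tau3_ps=7.8, f_exc=0.3)


@pytest.fixture(scope="session")
def kalpha_grid() -> np.ndarray:
    return default_xes_grid("kalpha")


@pytest.fixture(scope="session")
def kbeta_grid() -> np.ndarray:
    return default_xes_grid("kbeta")


@pytest.fixture(scope="session")
def species_ls(kalpha_grid):
    return species_spectrum("kalpha", "LS", kalpha_grid)


@pytest.fixture(scope="session")
def species_hs(kalpha_grid):
    return species_spectrum("kalpha", "HS", kalpha_grid)


@pytest.fixture(scope="session")
def noiseless_pairs_200fs(xanes_truth):
    """Noiseless laser-off/on K-alpha pair at a 200 fs delay."""
    return synth_timeseries("kalpha", xanes_truth, delays=[0.2],
                            noise_level=0.0)[0]
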