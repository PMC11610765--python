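import numpy as np
import pytest

from qband import fixtures
from qband.kinetics import InstrumentModel, KineticScheme, SpeciesSpectra
from qband.spectral import VibronicBand


@pytest.fixture(scope="session")
def band_system():
    system, axis = fixtures.load_band_system()
    return system, axis


@pytest.fixture(scope="session")
def qy_band():
    return VibronicBand(
        E00=14925.0, omega_vib=1250.0, huang_rhys=0.28, sigma=270.0,
        tdm_angle=17.0, amplitude=1.0, n_quanta=3, name="Q_y",
    )


@pytest.fixture()
def simple_scheme():
    return KineticScheme(lifetimes=[500.0, 5000.0], topology="sequential")


@pytest.fixture()
def simple_species():
    axis = np.linspace(14000.0, 20000.0, 60)
    s1 = -np.exp(-0.5 * ((axis - 15000.0) / 400.0) ** 2)
    s2 = -1.2 * np.exp(-0.5 * ((axis - 15400.0) / 350.0) ** 2)
    return SpeciesSpectra(axis=axis, spectra=np.vstack([s1, s2]), kind="SAS")


@pytest.fixture()
def instrument():
    return InstrumentModel(irf_fwhm=30.0, t0=0.0)
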