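import numpy as np
import pytest

from riverdom.eem import EEMSpectrum
from riverdom.parafac import EEMStack
from riverdom.synthetic import generate_eem_dataset, recovery_fluorophores


@pytest.fixture(scope="session")
def recovery_dataset():
    """Three-component synthetic EEM stack, n=20, 1% noise, no scatter."""
    eems, truth = generate_eem_dataset(
        n_samples=20, fluorophores=recovery_fluorophores(),
        scatter=False, seed=42)
    return eems, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exactly trilinear three-component stack (no noise, no scatter)."""
    eems, truth = generate_eem_dataset(
        n_samples=20, fluorophores=recovery_fluorophores(),
        noise_sd=0.0, scatter=False, seed=7)
    return eems, truth


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_dataset):
    eems, _ = noiseless_dataset
    return EEMStack(eems)


def constant_eem(value=1.0, ex=None, em=None, sample_id="const"):
    """Flat EEM covering the index wavelength windows."""
    if ex is None:
        ex = np.arange(240.0, 411.0, 10.0)
    if em is None:
        em = np.arange(280.0, 551.0, 5.0)
    grid = np.full((len(ex), len(em)), float(value))
    return EEMSpectrum(ex=np.asarray(ex, float), em=np.asarray(em, float),
                      intensity=grid, sample_id=sample_id)


@pytest.fixture
def flat_eem():
    return constant_eem()
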