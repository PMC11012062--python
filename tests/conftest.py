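import numpy as np
import pytest

from specfuse.io import SpectralDataset
from specfuse.simulate import MixtureModelParams, simulate_dataset


@pytest.fixture(scope="session")
def small_mixture():
    """Desk-scale mixture dataset: 40 samples on a 51-point grid."""
    params = MixtureModelParams(
        n_samples=40,
        wavelengths=np.arange(600.0, 701.0, 2.0),
        noise_sd=1e-4,
        seed=11,
    )
    return simulate_dataset(params)


@pytest.fixture()
def toy_dataset():
    """Tiny hand-checkable dataset."""
    wl = np.array([600.0, 650.0, 700.0, 750.0, 800.0])
    X = np.array([
        [0.10, 0.20, 0.40, 0.20, 0.10],
        [0.15, 0.30, 0.55, 0.31, 0.16],
        [0.05, 0.12, 0.30, 0.12, 0.06],
    ])
    return SpectralDataset(wl, X, ["a", "b", "c"], np.array([10.0, 12.0, 9.0]))
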