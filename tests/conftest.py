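import numpy as np
import pytest

from fusdeconv.simulate import simulate_dataset
from fusdeconv.structure import StructureConfig, autocorr_tensor, hankelize


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Hand-sized structural configuration for exact oracles."""
    return StructureConfig(L=2, M=2, Lp=3, K=3)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """M=3 dataset at 2 Hz with no artifact (infinite SNR)."""
    return simulate_dataset(M=3, snr_db=np.inf,
                            rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def noiseless_tensor(noiseless_dataset):
    cfg = StructureConfig(L=16, M=3)
    T = autocorr_tensor(hankelize(noiseless_dataset.Y, cfg.Lp), cfg.K)
    return T, cfg
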