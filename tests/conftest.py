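import numpy as np
import pytest

from dotprobe_eeg.synthetic_data import Montage, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


REDUCED_MONTAGE = Montage(
    labels=("F3", "F4", "C3", "C4", "Pz", "P7", "P8", "O1", "O2"),
    positions=((-0.4, 0.55), (0.4, 0.55), (-0.5, 0.0), (0.5, 0.0),
               (0.0, -0.5), (-0.81, -0.59), (0.81, -0.59),
               (-0.31, -0.95), (0.31, -0.95)))


@pytest.fixture(scope="session")
def reduced_montage():
    """9-channel montage (incl. Pz and both coupled pairs) for fast tests."""
    return REDUCED_MONTAGE


@pytest.fixture
def small_config(reduced_montage):
    """Two tiny groups on the reduced montage; defaults otherwise."""
    return SimulationConfig(n_hsa=3, n_lsa=2, montage=reduced_montage, seed=42)
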