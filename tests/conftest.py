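import numpy as np
import pytest

from alphasep import GroundTruthConfig, Montage, default_montage


@pytest.fixture(scope="session")
def montage() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def small_montage() -> Montage:
    """12-channel montage: both posterior groups plus two midline channels."""
    return Montage(
        channel_names=(
            "O1", "P3", "P7", "PO3", "PO7",
            "O2", "P4", "P8", "PO4", "PO8",
            "Cz", "Pz",
        ),
        stim_cluster=("O2", "P4", "P8", "PO4", "PO8"),
    )


@pytest.fixture
def small_config(small_montage) -> GroundTruthConfig:
    """Fast 2-condition configuration matched to the 12-channel montage."""
    return GroundTruthConfig(
        n_trials_per_condition=20,
        n_conditions=2,
        n_channels=small_montage.n_channels,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
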