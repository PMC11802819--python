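import numpy as np
import pytest

from bruteeg import EpochDataset, SynthConfig, generate


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Small but fully structured generator config used across tests."""
    return SynthConfig(
        n_subjects=4,
        n_channels=8,
        sfreq=128.0,
        epoch_seconds=0.5,
        trials_per_class_range=(10, 12),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg) -> EpochDataset:
    return generate(small_cfg)


@pytest.fixture
def tiny_ds() -> EpochDataset:
    """Three deterministic trials, two channels, four samples."""
    rng = np.random.default_rng(0)
    return EpochDataset(
        data=rng.standard_normal((3, 2, 4)),
        labels=[0, 1, 2],
        subjects=[1, 1, 2],
        sfreq=128.0,
        channel_names=["c1", "c2"],
    )


def make_axis_dataset(n_per_class: int = 4, scale: float = 5.0) -> EpochDataset:
    """Two-class toy whose trial covariances are exactly diag(4,1)/5 vs diag(1,4)/5.

    Channel rows are orthogonal patterns with squared norms 8 and 2 over four
    samples, so X @ X.T = diag(8, 2) (trace-normalised: diag(0.8, 0.2));
    class 1 swaps the channels.  Only classes 0 and 1 are populated.
    """
    strong = np.array([2.0, -2.0, 2.0, -2.0]) / np.sqrt(2)
    weak = np.array([1.0, 1.0, -1.0, -1.0]) / np.sqrt(2)
    trial0 = np.stack([strong, weak])  # cov diag(4,1) * 2/5 scale
    trial1 = np.stack([weak, strong])
    data = np.stack([trial0] * n_per_class + [trial1] * n_per_class)
    labels = [0] * n_per_class + [1] * n_per_class
    return EpochDataset(
        data=data,
        labels=labels,
        subjects=[1] * (2 * n_per_class),
        sfreq=4.0,
        channel_names=["cA", "cB"],
    )
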