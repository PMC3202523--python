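import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic train/val/test split shared across tests."""
    from ecgfusion.datasets import make_split_dataset
    return make_split_dataset(n_train_per_class=150, n_val_per_class=30,
                              n_test=900, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
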