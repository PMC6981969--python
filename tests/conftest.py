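import numpy as np
import pytest

from qsarstack import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """200-compound synthetic dataset with clear planted signal."""
    spec = synthetic.SyntheticSpec(
        n_active=60,
        n_inactive=140,
        n_informative=8,
        n_noise=20,
        n_quasi_constant=5,
        n_correlated_pairs=3,
        effect_size=1.5,
        seed=42,
    )
    return synthetic.generate_labeled_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
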