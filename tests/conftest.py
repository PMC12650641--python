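import numpy as np
import pytest

from tanet.backbone import ModelConfig
from tanet.synthetic import generate_feature_dataset


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """A shrunken architecture (same topology) for fast training tests."""
    return ModelConfig(eeg_channels=8, windows=10, conv_channels=(8, 16),
                       pool_target=(4, 10), d_model=32, n_heads=4,
                       ffn_expansion=2, n_blocks=1, classifier_dims=(16, 8),
                       mca_att_dim=8)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Strongly separable 3-class features matching ``tiny_config``."""
    rng = np.random.default_rng(7)
    n, shape = 120, (5, 8, 10)
    labels = np.repeat(np.arange(3), n // 3)
    de = rng.standard_normal((n,) + shape)
    psd_raw = rng.standard_normal((n,) + shape)
    for cls in range(3):
        de[labels == cls, cls % 5, 2 * cls:2 * cls + 2, :] += 3.0
        psd_raw[labels == cls, cls % 5, 2 * cls:2 * cls + 2, :] += 3.0
    order = rng.permutation(n)
    return de[order], np.logaddexp(0, psd_raw[order]), labels[order]


@pytest.fixture(scope="session")
def seed_features_small():
    """Full-size seed_like tensors, few trials (shape checks / forward)."""
    de, psd, y = generate_feature_dataset("seed_like", 4, 2.0, seed=3)
    return de, psd, y
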