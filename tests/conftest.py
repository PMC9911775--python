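import numpy as np
import pytest

from dcpha import CodeMatrix, LabelSet, ModelConfig, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_codes(rng):
    """Two modalities of relaxed codes plus labels for a tiny batch."""
    n, k = 5, 4
    codes = [CodeMatrix(rng.uniform(-0.95, 0.95, size=(n, k)), modality_index=m)
             for m in range(2)]
    labels = LabelSet.from_class_index(rng.integers(0, 2, size=n), 2)
    return codes, labels


@pytest.fixture
def binary_codes(rng):
    n, k = 6, 8
    codes = [CodeMatrix(np.sign(rng.normal(size=(n, k))) + (rng.normal(size=(n, k)) == 0),
                        modality_index=m, is_binary=False) for m in range(2)]
    # force exact ±1
    fixed = []
    for m, c in enumerate(codes):
        vals = np.where(c.values >= 0, 1.0, -1.0)
        fixed.append(CodeMatrix(vals, modality_index=m, is_binary=True))
    return fixed


@pytest.fixture
def small_dataset():
    return generate(SyntheticConfig(n_subjects=30, n_classes=3, seed=11))


@pytest.fixture
def tiny_model_config():
    return ModelConfig(n_modalities=2, input_dim_or_shape=64, feature_dim=16,
                       code_bits=8, n_classes=3, backbone="mlp", seed=0)
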