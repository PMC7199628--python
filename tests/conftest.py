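"""Shared fixtures: small synthetic datasets sized for fast unit tests."""

import numpy as np
import pytest

from eegmatch.spectral import WelchConfig
from eegmatch.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Generator config at reduced segment length for fast tests."""
    return GeneratorConfig(n_samples=4096, seed=11)


@pytest.fixture(scope="session")
def small_welch() -> WelchConfig:
    return WelchConfig(fs=512.0, nperseg=512)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """8 template-eligible + 8 test normals and 8 abnormals."""
    return generate_dataset(small_cfg, n_templates=8, n_normal_test=8,
                            n_abnormal_test=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_probability_pairs(n_pairs: int, k: int, seed: int):
    """Seeded strictly-positive unit-sum vector pairs for metric checks."""
    gen = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        p = gen.uniform(0.05, 1.0, size=k)
        q = gen.uniform(0.05, 1.0, size=k)
        pairs.append((p / p.sum(), q / q.sum()))
    return pairs
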