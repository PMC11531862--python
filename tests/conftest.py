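import numpy as np
import pytest

from mtloc import SimConfig, generate_corpus, model_config_for_sim, samples_from_corpus


@pytest.fixture(scope="session")
def tiny_sim():
    return SimConfig(n_proteins=16, length_range=(12, 20), seed=5)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_sim):
    return generate_corpus(tiny_sim)


@pytest.fixture(scope="session")
def tiny_samples(tiny_sim, tiny_corpus):
    return samples_from_corpus(tiny_corpus)


@pytest.fixture(scope="session")
def tiny_config(tiny_sim):
    return model_config_for_sim(tiny_sim, d_p=16, h_d=2, d_fe=8, d_f=8,
                                h_ki=2, seed=7, epochs=2, batch_size=4,
                                learning_rate=1e-3)


def random_backbone(rng, n, step=3.8):
    """Loose random chain used by graph tests (not the package generator)."""
    steps = rng.standard_normal((n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([[0, 0, 0], np.cumsum(steps * step, axis=0)])
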