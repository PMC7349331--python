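"""Shared fixtures: optical setup and small simulated corpora/models.

Everything is generated at test time with fixed seeds; session scope keeps
the simulation cost paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dlsann import OpticalSetup, TrainingCorpus, generate_training_corpus, train


@pytest.fixture(scope="session")
def setup() -> OpticalSetup:
    """He-Ne laser at 90 degrees into water at 22 C, sampled at 16 kHz."""
    return OpticalSetup()


@pytest.fixture(scope="session")
def small_corpus(setup) -> TrainingCorpus:
    """Coarse 24-series corpus (25-6000 nm, step 250 nm) for fast ANN tests."""
    return generate_training_corpus(
        setup, d_min=25e-9, d_max=6000e-9, step=250e-9, master_seed=42
    )


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A quickly trained model; adequate for pipeline mechanics, not accuracy."""
    model, report = train(small_corpus, seed=7, max_iterations=40)
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
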