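"""Shared fixtures: small synthetic datasets and models.

Session scope keeps the expensive artifacts (a trained group-A model)
to a single build per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from mgeclass import model as mdl
from mgeclass import simulate as sim


@pytest.fixture(scope="session")
def dataset_a():
    """Balanced, well-separated group-A dataset: 250 fragments/class."""
    return sim.simulate_dataset("A", 250, seed=11)


@pytest.fixture(scope="session")
def split_a(dataset_a):
    rng = np.random.default_rng(5)
    frags = list(dataset_a.fragments)
    idx = rng.permutation(len(frags))
    cut = int(0.75 * len(frags))
    return ([frags[i] for i in idx[:cut]], [frags[i] for i in idx[cut:]])


@pytest.fixture(scope="session")
def trained_model_a(split_a):
    train_frags, _ = split_a
    model = mdl.build_architecture("A", seed=0)
    mdl.train(model, train_frags, epochs=5, batch_size=128, seed=0)
    return model


@pytest.fixture(scope="session")
def untrained_models():
    """Seeded but untrained models for all three groups (deterministic)."""
    return {g: mdl.build_architecture(g, seed=3) for g in ("A", "B", "C")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
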