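"""Shared fixtures: synthetic data factories and session-scoped trained models."""

from __future__ import annotations

import numpy as np
import pytest

from cpsearch import encoder, structio

# conditions of the desk-scale training study used across the suite
TRAIN_FAMILIES = 30
TRAIN_MEMBERS = 8
TRAIN_LENGTH = 80
TRAIN_NOISE_SD = 0.3
TRAIN_EPOCHS = 100
TRAIN_SEED = 42

MODEL_KW = dict(
    n_layers=4,
    hidden_dim=64,
    embed_dim=64,
    epochs=TRAIN_EPOCHS,
    batch_families=8,
    members_per_family=4,
)


def make_labeled_set(
    n_families: int, members: int, length: int, noise_sd: float, seed: int
) -> list[structio.CaTrace]:
    """Independent labeled families; one master seed spawns per-family seeds."""
    rng = np.random.default_rng(seed)
    traces: list[structio.CaTrace] = []
    for f in range(n_families):
        traces += structio.make_synthetic_family(
            members,
            length,
            noise_sd,
            int(rng.integers(0, 2**31 - 1)),
            family_label=f"x.{f + 1}.1.1",
            id_prefix=f"f{f}",
        )
    return traces


def random_trace(rng: np.random.Generator, n: int, trace_id: str = "rw") -> structio.CaTrace:
    """Self-avoiding-ish random walk at Cα spacing — a 'random fold' decoy."""
    steps = rng.normal(size=(n - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return structio.CaTrace(id=trace_id, coords=np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]))


@pytest.fixture(scope="session")
def training_set() -> list[structio.CaTrace]:
    return make_labeled_set(TRAIN_FAMILIES, TRAIN_MEMBERS, TRAIN_LENGTH, TRAIN_NOISE_SD, TRAIN_SEED)


@pytest.fixture(scope="session")
def augmented_model(training_set) -> encoder.TrainedModel:
    """CP-invariant encoder: synCP augmentation on."""
    config = encoder.ModelConfig(**MODEL_KW, seed=1, syncp_augment=True)
    return encoder.train(training_set, config)


@pytest.fixture(scope="session")
def baseline_model(training_set) -> encoder.TrainedModel:
    """CP-sensitive baseline: same data and architecture, augmentation off."""
    config = encoder.ModelConfig(**MODEL_KW, seed=1, syncp_augment=False)
    return encoder.train(training_set, config)


@pytest.fixture(scope="session")
def untrained_model() -> encoder.TrainedModel:
    return encoder.fresh_model(encoder.ModelConfig(n_layers=3, hidden_dim=64, embed_dim=64, seed=7))

def make_block_pair_trace(seed: int, duplicated: bool, block_len: int = 28):
    """One chain: block — linker — second block — random-walk tail.

    With ``duplicated`` the second block is a rigidly rotated copy of the
    first; otherwise it is an irregular coil of the same length, giving a
    control trace with an identical sequence layout (same index offsets, so
    any positional carrier in the node embeddings cancels in the contrast).
    Returns (trace, indices_of_block1, indices_of_block2).
    """
    rng = np.random.default_rng(seed + 1)
    block = structio.make_synthetic_family(1, block_len, 0.0, seed)[0].coords
    block = block - block[0]
    if duplicated:
        second = block
    else:
        second = random_trace(np.random.default_rng(seed + 5000), block_len).coords
        second = second - second[0]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    n_link = 6
    linker = block[-1] + 3.8 * direction * np.arange(1, n_link + 1)[:, None]
    R = structio._random_rotation(rng)
    block2 = (second @ R.T) + linker[-1] + 3.8 * direction
    tail_steps = rng.normal(size=(10, 3))
    tail_steps = 3.8 * tail_steps / np.linalg.norm(tail_steps, axis=1, keepdims=True)
    tail = block2[-1] + np.cumsum(tail_steps, axis=0)
    coords = np.vstack([block, linker, block2, tail])
    trace = structio.CaTrace(id=f"blocks{seed}{int(duplicated)}", coords=coords)
    s1 = np.arange(block_len)
    s2 = np.arange(block_len + n_link, 2 * block_len + n_link)
    return trace, s1, s2
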