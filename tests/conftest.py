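"""Shared fixtures: synthetic leaves, member tables, separable image sets."""

import numpy as np
import pytest

from leaffuse import (
    LabeledDataset,
    SyntheticLeafSpec,
    gen_leaf,
    gen_member_probs,
)


@pytest.fixture(scope="session")
def skewed_member_table():
    """Two members with accuracies 0.95 / 0.25 on 2000 four-class samples.

    The canonical fixture for fusion and search: the loss-optimal mixture
    provably favours the accurate member.
    """
    rng = np.random.default_rng(42)
    labels = rng.integers(0, 4, 2000)
    return gen_member_probs(labels, [0.95, 0.25], K=4, concentration=20.0, seed=42)


@pytest.fixture(scope="session")
def leaf_30():
    """One leaf with a 30% planted chlorotic fraction."""
    return gen_leaf(SyntheticLeafSpec(symptom_fraction=0.30, seed=7))


@pytest.fixture(scope="session")
def healthy_leaf():
    return gen_leaf(SyntheticLeafSpec(symptom_fraction=0.0, seed=7))


def make_separable_dataset(n_per_class: int = 20, seed: int = 0) -> LabeledDataset:
    """Two image classes separated by colour (dark green vs bright yellow).

    Linearly separable in any reasonable feature space, so a trained head
    must reach near-perfect validation accuracy.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for label, base in enumerate([(30, 90, 30), (200, 190, 60)]):
        for _ in range(n_per_class):
            img = np.full((32, 32, 3), base, dtype=float)
            img += rng.normal(0, 8, size=img.shape)
            samples.append((np.clip(img, 0, 255).astype(np.uint8), label))
    return LabeledDataset(samples=samples, class_names=["dark", "bright"])


@pytest.fixture(scope="session")
def separable_dataset():
    return make_separable_dataset()
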