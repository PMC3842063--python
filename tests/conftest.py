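"""Shared fixtures: small phantoms and a quickly trained model archive.

The small fixtures keep unit tests fast; the full-scale end-to-end runs
live in test_acceptance.py with their own session fixtures.
"""

import numpy as np
import pytest

import mammotrace as mt

#: tiny hyperparameter grid for unit-test model fits
TINY_GRID = {"C": [2.0**-1, 2.0**5], "gamma": [2.0**-13, 2.0**-9]}


@pytest.fixture(scope="session")
def small_dataset():
    """3 train + 2 test phantoms at 160x160 (deterministic)."""
    config = mt.PhantomConfig(size=(160, 160))
    data = mt.generate_dataset(3, 2, config, seed=11)
    return data["samples"]


@pytest.fixture(scope="session")
def small_archive(small_dataset):
    """Model archive trained on the small phantoms (reduced grid/samples)."""
    train = small_dataset["train"]
    return mt.train_archive(
        [s.image for s in train],
        [s.gt_boundary for s in train],
        n_negatives_per_image=300,
        seed=11,
        max_per_class=500,
        grid=TINY_GRID,
    )


@pytest.fixture(scope="session")
def blob_samples():
    """Two well-separated 2-D Gaussian blobs as labeled descriptor samples."""
    rng = np.random.default_rng(4)
    n = 200
    pos = rng.normal(loc=[3.0, 0.0], scale=0.1, size=(n, 2))
    neg = rng.normal(loc=[0.0, 0.0], scale=0.1, size=(n, 2))
    samples = [
        mt.LabeledSample(d, mt.texture.BOUNDARY, "blob", (0, i))
        for i, d in enumerate(pos)
    ] + [
        mt.LabeledSample(d, mt.texture.NONBOUNDARY, "blob", (1, i))
        for i, d in enumerate(neg)
    ]
    return samples


#: logarithmic grid with the kernel-width range matched to the 2-D
#: unit-scale blob geometry (squared distances ~O(1-10)); the package
#: default grid spans widths sized for 1024-bin count descriptors
BLOB_GRID = {"C": 2.0 ** np.arange(0, 11, 2), "gamma": 2.0 ** np.arange(-5, 2, 2)}


@pytest.fixture(scope="session")
def blob_grid():
    return BLOB_GRID


@pytest.fixture(scope="session")
def blob_model(blob_samples):
    return mt.train_texture_model(blob_samples, grid=BLOB_GRID, seed=4)
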