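import numpy as np
import pytest

from seqrsa.design import Schema, make_schedule
from seqrsa.simulate import (
    GeneratorConfig,
    PatternDataset,
    RegionLayout,
    generate_patterns,
)


@pytest.fixture(scope="session")
def schedule12():
    return make_schedule(2, Schema.North, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_dataset(schedule12):
    """2 participants x 12 weddings x 3 stages over 5 voxels, pure noise."""
    gen = np.random.default_rng(99)
    mask = np.ones((5, 1, 1), dtype=bool)
    patterns = gen.standard_normal((2, 12, 3, 5))
    return PatternDataset(patterns=patterns, schedule=schedule12, mask=mask)


def bar_layout() -> RegionLayout:
    """Five 5x5x5 region blocks along x in a 31x7x7 grid, 1-voxel gaps."""
    labels = np.zeros((31, 7, 7), dtype=np.int16)
    for i, label in enumerate((1, 2, 3, 4, 5)):
        x = 1 + 6 * i
        labels[x : x + 5, 1:6, 1:6] = label
    layout = RegionLayout(labels)
    layout.validate()
    return layout


def single_region_layout(label: int, shape=(7, 7, 7)) -> RegionLayout:
    labels = np.zeros(shape, dtype=np.int16)
    labels[1:6, 1:6, 1:6] = label
    layout = RegionLayout(labels)
    layout.validate()
    return layout


@pytest.fixture(scope="session")
def planted_dataset():
    """Compact all-codes dataset: 8 participants on the bar layout."""
    cfg = GeneratorConfig(n_participants=8, layout=bar_layout(), seed=11)
    return cfg, generate_patterns(cfg)


def center_region_labels(dataset, centers: np.ndarray) -> np.ndarray:
    return dataset.region_labels[centers[:, 0], centers[:, 1], centers[:, 2]]


def deep_background(dataset, centers: np.ndarray) -> np.ndarray:
    """Centers whose whole 5-cube avoids every labeled region."""
    from scipy import ndimage

    touched = ndimage.maximum_filter(
        (dataset.region_labels > 0).astype(np.int8), size=5, mode="constant"
    )
    return touched[centers[:, 0], centers[:, 1], centers[:, 2]] == 0
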