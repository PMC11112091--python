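"""Shared fixtures: analytic shapes, toy genome, and the synthetic cell bank."""

import numpy as np
import pandas as pd
import pytest

from gliamorph.image import crop_and_isolate, preprocess
from gliamorph.morphometry import profile_cells
from gliamorph.synthetic import (
    degrade_to_grayscale,
    generate_cell_bank,
    make_toy_genome,
)


def rasterized_disk(radius: int, pad: int = 10) -> np.ndarray:
    size = 2 * radius + 2 * pad + 1
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius * radius


def plus_pentomino(arm: int = 50) -> np.ndarray:
    """Plus sign of five arm×arm squares (3×3 arm bounding box)."""
    size = 3 * arm + 2 * 20
    img = np.zeros((size, size), dtype=bool)
    o = 20
    img[o + arm:o + 2 * arm, o:o + 3 * arm] = True
    img[o:o + 3 * arm, o + arm:o + 2 * arm] = True
    return img


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome()


@pytest.fixture(scope="session")
def cell_bank():
    """50 ramified + 50 ameboid silhouettes with ground-truth labels."""
    return generate_cell_bank(n_per_class=50, master_seed=11)


@pytest.fixture(scope="session")
def full_path_profiles(cell_bank):
    """Panel measured through the complete image path.

    Each ground-truth silhouette is degraded to noisy grayscale,
    re-binarized, cropped/isolated, and profiled — the same route real
    microscopy crops would take.  Returns (profiles, class labels).
    """
    pairs, labels = cell_bank
    recovered = []
    for pair, lab in zip(pairs, labels):
        gray = degrade_to_grayscale(pair, seed=lab.seed + 1)
        mask = preprocess(gray)
        recovered.append(crop_and_isolate(mask, frame=340, cell_id=pair.cell_id))
    profiles = profile_cells(recovered)
    groups = pd.Series([lab.class_label for lab in labels], index=profiles.index,
                       name="group")
    return profiles, groups
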