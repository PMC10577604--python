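"""Shared fixtures: easy synthetic tiles and once-per-session trained models."""

from __future__ import annotations

import numpy as np
import pytest

from folliscape.detection import train_detector
from folliscape.phenotyping import extract_patches, train_classifier
from folliscape.synthetic_data import (
    SceneConfig,
    generate_cell_map,
    render_deconvoluted_tiles,
)

UM_PER_PIXEL = 0.5


def easy_tile(seed: int, width: float = 128.0, height: float = 128.0,
              density: float = 4.0, pos_label: str = "CD8+", neg_label: str = "FOXP3+"):
    """An "easy" benchmark tile: bright well-separated blobs, light noise.

    Returns (2-channel CD8-plane image, GroundTruth). Cells have a 6 μm
    hard-core separation so every nucleus is individually resolvable.
    """
    cfg = SceneConfig(
        width_um=width, height_um=height, n_follicles=0,
        phenotype_densities={pos_label: (0.0, density), neg_label: (0.0, density)},
        min_separation_um=6.0, noise_sd=0.02, background_level=0.05, seed=seed,
    )
    truth = generate_cell_map(cfg)
    img = render_deconvoluted_tiles(truth)["CD8"]
    return img, truth


@pytest.fixture(scope="session")
def trained_detector():
    """Reference detector trained on 20 easy tiles (seed 0, 10 epochs)."""
    tiles = [easy_tile(s) for s in range(20)]
    return train_detector(
        [img for img, _ in tiles],
        [t.cells[["x_um", "y_um"]].to_numpy() for _, t in tiles],
        {"seed": 0, "epochs": 10, "steps_per_epoch": 30},
    )


@pytest.fixture(scope="session")
def trained_classifier():
    """Reference patch classifier trained on ~2k easy patches."""
    patches, labels = [], []
    for s in range(10):
        img, truth = easy_tile(s)
        patches.append(extract_patches(img, truth.cells[["x_um", "y_um"]].to_numpy(),
                                       UM_PER_PIXEL, 28))
        labels.append(truth.cells["CD8_pos"].to_numpy().astype(int))
    return train_classifier(np.vstack(patches), np.concatenate(labels),
                            {"seed": 0, "epochs": 3})
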