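"""Shared fixtures: small synthetic scenes and a quickly trained model."""

from __future__ import annotations

import numpy as np
import pytest

import phenolstm as pl
from phenolstm.profiles import PhenologyProfile


def summer_signal_profiles(
    noise_sd: float = 0.05,
    amplitudes: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75),
    greenup: float = 250.0,
    senescence: float = 330.0,
    rate: float = 0.15,
) -> list[PhenologyProfile]:
    """Classes that differ only in summer NDVI amplitude, with class signal
    carried solely by B4/B8 (hence NDVI and E_NDVI): all other bands get
    class-independent values."""
    names = ["FLAT", "LOW", "MID", "HIGH", "XTRA"][: len(amplitudes)]
    return [
        PhenologyProfile(
            name, 0.15, amp, greenup, senescence, rate, rate,
            band_noise_sd=noise_sd, informative_bands=frozenset(),
        )
        for name, amp in zip(names, amplitudes)
    ]


@pytest.fixture(scope="session")
def tiny_scene() -> pl.LabeledScene:
    """16x16 grid, 4x4 parcels, 4 classes — cheap structural test bed."""
    cfg = pl.SceneConfig(
        grid_height=16, grid_width=16, parcel_size=4,
        profiles=summer_signal_profiles(0.02),
        class_proportions=np.full(4, 0.25), seed=5,
    )
    return pl.generate_scene(cfg)


@pytest.fixture(scope="session")
def two_class_cubes():
    """Standardized train/test cubes for two well-separated classes
    (disjoint summer NDVI amplitudes)."""
    cfg = pl.SceneConfig(
        grid_height=16, grid_width=16, parcel_size=4,
        profiles=summer_signal_profiles(0.02, amplitudes=(0.1, 0.7)),
        class_proportions=np.full(2, 0.5), seed=17,
    )
    scene = pl.generate_scene(cfg)
    cube = pl.assemble_features(scene)
    tr, te = pl.split_train_test(scene, 0.7, "pixel", 3)
    train_cube = pl.standardize(cube.subset(tr))
    test_cube = pl.standardize(cube.subset(te), (train_cube.mean, train_cube.scale))
    return train_cube, test_cube


@pytest.fixture(scope="session")
def small_trained_model(two_class_cubes):
    """A small BiLSTM trained to high accuracy on the two-class scene."""
    train_cube, _ = two_class_cubes
    cfg = pl.TrainingConfig(
        n_layers=1, hidden_size=8, epochs=20, batch_size=32,
        dropout_rate=0.2, validation_fraction=0.0, seed=21,
    )
    model, history = pl.train(cfg, train_cube)
    return model, history
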