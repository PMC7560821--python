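"""Build the 14-predictor x 30-timestep feature representation.

Per date and pixel: the 12 surface-reflectance bands, NDVI, and E_NDVI (the
Shannon entropy of NDVI in a 5x5 spatial window — an image texture measure).
Features are z-scored on the training split only, to avoid leakage.
"""

import numpy as np

import phenolstm as pl

scene = pl.generate_scene(pl.SceneConfig(grid_height=32, grid_width=32,
                                         parcel_size=8, seed=2))
cube = pl.assemble_features(scene, window=5, n_bins=16)
print(f"feature cube: {cube.values.shape} (samples, timesteps, features)")
print("feature order:", ", ".join(cube.feature_names))

train_idx, test_idx = pl.split_train_test(scene, 0.7, "pixel", seed=0)
train = pl.standardize(cube.subset(train_idx))
test = pl.standardize(cube.subset(test_idx), (train.mean, train.scale))
print(f"train {train.n_samples} / test {test.n_samples} samples")
print("train means after z-scoring (should be ~0):",
      np.abs(train.values.mean(axis=(0, 1))).max())

ent = cube.values[:, :, cube.feature_names.index("E_NDVI")]
print(f"E_NDVI range: {ent.min():.2f}..{ent.max():.2f} bits "
      f"(0 = locally uniform NDVI, higher = heterogeneous, e.g. parcel edges)")
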