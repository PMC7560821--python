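"""Train the stacked bidirectional LSTM classifier and report accuracy.

A scaled-down run: 4 well-separated classes, a 48x48 scene, a 2-layer BiLSTM
with 24 hidden units per direction.  Expect >95% test accuracy in ~1 minute.
"""

import numpy as np

import phenolstm as pl
from phenolstm.profiles import PhenologyProfile

profiles = [
    PhenologyProfile(name, 0.15, amp, 250, 330, 0.15, 0.15, band_noise_sd=0.02)
    for name, amp in [("FLAT", 0.0), ("LOW", 0.25), ("MID", 0.5), ("HIGH", 0.75)]
]
scene = pl.generate_scene(pl.SceneConfig(
    grid_height=48, grid_width=48, parcel_size=8,
    profiles=profiles, class_proportions=np.full(4, 0.25), seed=11,
))
cube = pl.assemble_features(scene)
train_idx, test_idx = pl.split_train_test(scene, 0.7, "pixel", seed=2)
train_cube = pl.standardize(cube.subset(train_idx))
test_cube = pl.standardize(cube.subset(test_idx), (train_cube.mean, train_cube.scale))

config = pl.TrainingConfig(n_layers=2, hidden_size=24, epochs=15,
                           batch_size=128, seed=7)
model, history = pl.train(config, train_cube)
print(f"trained {len(history['train_loss'])} epochs; "
      f"final train loss {history['train_loss'][-1]:.4f}")

report = pl.evaluate(model, test_cube, n_train=train_cube.n_samples,
                     split_mode="pixel")
print(f"overall accuracy: {report.overall_accuracy:.2f}% "
      f"on {report.n_test} test pixels")
print(report.to_table().to_string(index=False))
# precision = of the pixels predicted as a class, the share truly that class;
# recall = of a class's true pixels, the share recovered; F-1 = harmonic mean.
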