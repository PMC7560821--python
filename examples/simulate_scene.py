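"""Generate a synthetic labeled land-use scene and inspect its structure.

The generator plants class-specific seasonal NDVI cycles (rice peaking in
summer, winter cereals in winter-spring, flat trajectories for permanent
vegetation) on a parcel-tiled grid with Gaussian band noise.
"""

import numpy as np

import phenolstm as pl

config = pl.SceneConfig(grid_height=48, grid_width=48, parcel_size=8, seed=1)
scene = pl.generate_scene(config)

print(f"scene: {scene.shape[0]}x{scene.shape[1]} pixels, "
      f"{scene.n_dates} dates, {len(scene.band_names)} bands")
counts = np.bincount(scene.labels.ravel(), minlength=len(scene.class_names))
print("pixels per class:")
for name, n in sorted(zip(scene.class_names, counts), key=lambda x: -x[1]):
    print(f"  {name:4s} {n:5d}")

# seasonal NDVI course of the two most contrasting classes
b8 = scene.reflectance[..., scene.band_names.index("B8")]
b4 = scene.reflectance[..., scene.band_names.index("B4")]
ndvi = pl.compute_ndvi(b8, b4)
for name in ("RIC", "FOR"):
    k = scene.class_names.index(name)
    curve = ndvi[scene.labels == k].mean(axis=0)
    peak = int(np.argmax(curve))
    print(f"{name}: NDVI min {curve.min():.2f}, max {curve.max():.2f}, "
          f"peak at day {scene.date_list[peak]:.0f} of the agronomic year")
# Rice peaks in late summer (high day number since day 0 = September 1);
# the forest curve is flat, which is what makes natural classes hard to split.
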