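"""The 14-predictor × 30-timestep input representation.

Each pixel contributes a sequence of 14 features per acquisition date: the 12
surface-reflectance bands, NDVI = (B8-B4)/(B8+B4), and E_NDVI — the Shannon
entropy of NDVI in a local spatial window, a texture measure of NDVI
heterogeneity around the pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .profiles import BAND_NAMES
from .simulate import LabeledScene

#: Frozen feature order: 12 bands, then NDVI (index 12) and E_NDVI (index 13).
FEATURE_NAMES: tuple[str, ...] = BAND_NAMES + ("NDVI", "E_NDVI")

NDVI_INDEX = FEATURE_NAMES.index("NDVI")
ENDVI_INDEX = FEATURE_NAMES.index("E_NDVI")


@dataclass
class FeatureCube:
    """``(n_samples, n_timesteps, n_features)`` predictor tensor.

    ``sample_index`` maps each sample back to its ``(row, col)`` pixel;
    ``mean``/``scale`` hold the per-feature standardization statistics once
    :func:`standardize` has been applied (``None`` otherwise).
    """

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    sample_index: np.ndarray | None = None
    labels: np.ndarray | None = None
    class_names: list[str] | None = None
    date_list: np.ndarray | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_samples, n_timesteps, n_features)")
        if not np.isfinite(self.values).all():
            raise ValueError("FeatureCube contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def subset(self, idx: np.ndarray) -> "FeatureCube":
        """Row subset (e.g. a train/test split) sharing metadata."""
        return FeatureCube(
            values=self.values[idx],
            feature_names=self.feature_names,
            sample_index=None if self.sample_index is None else self.sample_index[idx],
            labels=None if self.labels is None else self.labels[idx],
            class_names=self.class_names,
            date_list=self.date_list,
            mean=self.mean,
            scale=self.scale,
        )


def compute_ndvi(b8, b4):
    """NDVI = (B8 - B4) / (B8 + B4), elementwise.

    Both inputs must be non-negative reflectances.  The degenerate dark-pixel
    case B8 + B4 = 0 maps to 0 by convention, keeping the pipeline total on
    clipped pixels.
    """
    b8 = np.asarray(b8, float)
    b4 = np.asarray(b4, float)
    if np.any(b8 < 0) or np.any(b4 < 0):
        raise ValueError("reflectances must be non-negative")
    total = b8 + b4
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, (b8 - b4) / np.where(total > 0, total, 1.0), 0.0)
    return out if out.ndim else float(out)


def ndvi_entropy(ndvi_map: np.ndarray, window: int = 5, n_bins: int = 16) -> np.ndarray:
    """Sliding-window Shannon entropy (bits) of an NDVI grid.

    Per pixel: histogram the NDVI values inside the centered ``window`` ×
    ``window`` neighbourhood into ``n_bins`` equal-width bins over
    ``[-1, 1]`` and return ``-sum p_k log2 p_k``.  Edges are handled by
    reflection padding; the output has the input's shape.
    """
    ndvi_map = np.asarray(ndvi_map, float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if window > min(ndvi_map.shape):
        raise ValueError(
            f"window {window} larger than grid {ndvi_map.shape}"
        )
    pad = window // 2
    padded = np.pad(ndvi_map, pad, mode="reflect")
    # digitize into equal-width bins over [-1, 1]; values at +1 fold into the last bin
    bins = np.clip(((padded + 1.0) / 2.0 * n_bins).astype(int), 0, n_bins - 1)
    windows = sliding_window_view(bins, (window, window))  # (H, W, w, w)
    h, w = ndvi_map.shape
    flat = windows.reshape(h, w, window * window)
    counts = (flat[..., :, None] == np.arange(n_bins)).sum(axis=2)  # (H, W, n_bins)
    p = counts / (window * window)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1) + 0.0  # +0.0 normalizes -0.0 entries


def assemble_features(
    scene: LabeledScene, window: int = 5, n_bins: int = 16
) -> FeatureCube:
    """Build the feature cube from a scene: per date, the 12 bands, NDVI per
    pixel, and E_NDVI computed on that date's full NDVI map; pixels are then
    flattened to samples in row-major order."""
    missing = [b for b in BAND_NAMES if b not in scene.band_names]
    if missing:
        raise ValueError(f"scene is missing band(s): {missing}")
    band_order = [scene.band_names.index(b) for b in BAND_NAMES]
    refl = scene.reflectance[..., band_order]  # (H, W, T, 12)
    h, w, T, _ = refl.shape
    values = np.empty((h * w, T, len(FEATURE_NAMES)))
    i_b8 = BAND_NAMES.index("B8")
    i_b4 = BAND_NAMES.index("B4")
    for d in range(T):
        bands_d = refl[:, :, d, :]
        ndvi_map = compute_ndvi(bands_d[..., i_b8], bands_d[..., i_b4])
        ent_map = ndvi_entropy(ndvi_map, window=window, n_bins=n_bins)
        values[:, d, : len(BAND_NAMES)] = bands_d.reshape(h * w, -1)
        values[:, d, NDVI_INDEX] = ndvi_map.ravel()
        values[:, d, ENDVI_INDEX] = ent_map.ravel()
    rows, cols = np.divmod(np.arange(h * w), w)
    return FeatureCube(
        values=values,
        sample_index=np.column_stack([rows, cols]),
        labels=scene.labels.ravel().copy(),
        class_names=list(scene.class_names),
        date_list=np.asarray(scene.date_list, float),
    )


def standardize(cube: FeatureCube, stats: tuple[np.ndarray, np.ndarray] | None = None) -> FeatureCube:
    """Per-feature z-scoring across all samples and timesteps.

    Without ``stats``, the mean/scale are fitted on *cube* (the training
    path) and recorded on the result; with ``stats = (mean, scale)`` they are
    applied unchanged (the validation path — prevents train/test leakage).
    A zero-variance feature gets scale 1 with a warning.
    """
    if stats is None:
        mean = cube.values.mean(axis=(0, 1))
        scale = cube.values.std(axis=(0, 1))
        zero = scale < 1e-12
        if zero.any():
            names = [cube.feature_names[j] for j in np.flatnonzero(zero)]
            warnings.warn(f"zero-variance feature(s) {names}; scale set to 1", stacklevel=2)
            scale = np.where(zero, 1.0, scale)
    else:
        mean, scale = (np.asarray(a, float) for a in stats)
    out = FeatureCube(
        values=(cube.values - mean) / scale,
        feature_names=cube.feature_names,
        sample_index=cube.sample_index,
        labels=cube.labels,
        class_names=cube.class_names,
        date_list=cube.date_list,
        mean=mean.copy(),
        scale=scale.copy(),
    )
    return out
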