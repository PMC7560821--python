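"""Readers and writers: HDF5 array containers, CSV exports, YAML configs,
and a thin GeoTIFF ingestion adapter for user-supplied real raster stacks."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import FeatureCube
from .profiles import BAND_NAMES, PhenologyProfile, SceneConfig
from .simulate import LabeledScene

__all__ = [
    "save_scene", "load_scene", "scene_to_csv",
    "save_cube", "load_cube", "cube_to_csv",
    "load_scene_config", "dump_scene_config",
    "read_geotiff_scene",
]


def save_scene(scene: LabeledScene, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "phenolstm-scene"
        f.attrs["version"] = 1
        f.create_dataset("reflectance", data=scene.reflectance, compression="gzip")
        f.create_dataset("labels", data=scene.labels)
        f.create_dataset("parcel_ids", data=scene.parcel_ids)
        f.create_dataset("date_list", data=scene.date_list)
        f.attrs["band_names"] = list(scene.band_names)
        f.attrs["class_names"] = list(scene.class_names)


def load_scene(path) -> LabeledScene:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "phenolstm-scene":
            raise ValueError(f"{path} is not a scene container")
        return LabeledScene(
            reflectance=f["reflectance"][...],
            labels=f["labels"][...],
            parcel_ids=f["parcel_ids"][...],
            band_names=tuple(str(b) for b in f.attrs["band_names"]),
            date_list=f["date_list"][...],
            class_names=[str(c) for c in f.attrs["class_names"]],
        )


def scene_to_csv(scene: LabeledScene, path) -> None:
    """One row per pixel-date with band columns, label, parcel and day."""
    h, w, T, nb = scene.reflectance.shape
    refl = scene.reflectance.reshape(h * w, T, nb)
    rows, cols = np.divmod(np.arange(h * w), w)
    rec = {
        "row": np.repeat(rows, T),
        "col": np.repeat(cols, T),
        "date_day": np.tile(scene.date_list, h * w),
        "label": np.repeat([scene.class_names[k] for k in scene.labels.ravel()], T),
        "parcel_id": np.repeat(scene.parcel_ids.ravel(), T),
    }
    flat = refl.reshape(h * w * T, nb)
    for j, b in enumerate(scene.band_names):
        rec[b] = flat[:, j]
    pd.DataFrame(rec).to_csv(path, index=False)


def save_cube(cube: FeatureCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "phenolstm-cube"
        f.attrs["version"] = 1
        f.create_dataset("values", data=cube.values, compression="gzip")
        f.attrs["feature_names"] = list(cube.feature_names)
        if cube.sample_index is not None:
            f.create_dataset("sample_index", data=cube.sample_index)
        if cube.labels is not None:
            f.create_dataset("labels", data=cube.labels)
        if cube.class_names is not None:
            f.attrs["class_names"] = list(cube.class_names)
        if cube.date_list is not None:
            f.create_dataset("date_list", data=cube.date_list)
        if cube.mean is not None:
            f.create_dataset("mean", data=cube.mean)
            f.create_dataset("scale", data=cube.scale)


def load_cube(path) -> FeatureCube:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "phenolstm-cube":
            raise ValueError(f"{path} is not a feature-cube container")
        return FeatureCube(
            values=f["values"][...],
            feature_names=tuple(str(n) for n in f.attrs["feature_names"]),
            sample_index=f["sample_index"][...] if "sample_index" in f else None,
            labels=f["labels"][...] if "labels" in f else None,
            class_names=[str(c) for c in f.attrs["class_names"]]
            if "class_names" in f.attrs else None,
            date_list=f["date_list"][...] if "date_list" in f else None,
            mean=f["mean"][...] if "mean" in f else None,
            scale=f["scale"][...] if "scale" in f else None,
        )


def cube_to_csv(cube: FeatureCube, path) -> None:
    """Flattened per-sample export: one column per feature@timestep."""
    n, T, F = cube.values.shape
    cols = {}
    if cube.sample_index is not None:
        cols["row"] = cube.sample_index[:, 0]
        cols["col"] = cube.sample_index[:, 1]
    if cube.labels is not None:
        names = cube.class_names or {}
        cols["label"] = [
            names[k] if cube.class_names else k for k in cube.labels
        ]
    flat = cube.values.reshape(n, T * F)
    for t in range(T):
        day = int(round(cube.date_list[t])) if cube.date_list is not None else t
        for j, fname in enumerate(cube.feature_names):
            cols[f"{fname}@d{day:03d}"] = flat[:, t * F + j]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scene configuration documents


def dump_scene_config(config: SceneConfig, path) -> None:
    doc = {
        "grid_height": config.grid_height,
        "grid_width": config.grid_width,
        "parcel_size": config.parcel_size,
        "n_dates": config.n_dates,
        "date_list": [float(d) for d in config.date_list],
        "seed": config.seed,
        "class_proportions": [float(p) for p in config.class_proportions],
        "profiles": [
            {
                "class_name": p.class_name,
                "ndvi_base": p.ndvi_base,
                "ndvi_amplitude": p.ndvi_amplitude,
                "greenup_day": p.greenup_day,
                "senescence_day": p.senescence_day,
                "greenup_rate": p.greenup_rate,
                "senescence_rate": p.senescence_rate,
                "band_noise_sd": p.band_noise_sd,
                "band_sum": p.band_sum,
                "informative_bands": sorted(p.informative_bands),
            }
            for p in config.profiles
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scene_config(path) -> SceneConfig:
    """Read a YAML (or JSON — a YAML subset) document into a SceneConfig."""
    doc = yaml.safe_load(Path(path).read_text())
    profiles = None
    if "profiles" in doc:
        profiles = []
        for p in doc["profiles"]:
            p = dict(p)
            if "informative_bands" in p:
                p["informative_bands"] = frozenset(p["informative_bands"])
            profiles.append(PhenologyProfile(**p))
    kwargs = {
        k: doc[k]
        for k in ("grid_height", "grid_width", "parcel_size", "n_dates", "seed")
        if k in doc
    }
    if "date_list" in doc:
        kwargs["date_list"] = np.asarray(doc["date_list"], float)
        kwargs.setdefault("n_dates", len(kwargs["date_list"]))
    if "class_proportions" in doc:
        kwargs["class_proportions"] = np.asarray(doc["class_proportions"], float)
    return SceneConfig(profiles=profiles, **kwargs)


# ---------------------------------------------------------------------------
# GeoTIFF ingestion adapter (optional path for real data)


def _nearest_resample(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample of a (h, w[, c]) array to *shape*."""
    h, w = arr.shape[:2]
    rows = np.minimum((np.arange(shape[0]) + 0.5) * h / shape[0], h - 1).astype(int)
    cols = np.minimum((np.arange(shape[1]) + 0.5) * w / shape[1], w - 1).astype(int)
    return arr[np.ix_(rows, cols)]


def read_geotiff_scene(
    band_paths: list, label_path, date_list, class_names: list[str] | None = None
) -> LabeledScene:
    """Build a :class:`LabeledScene` from per-date 12-band GeoTIFF rasters
    plus one label raster.

    ``band_paths`` lists one multiband raster per date, in date order; each
    must hold 12 bands in the standard order.  All rasters are resampled by
    nearest neighbour to the label raster's grid.  Parcel ids are not
    available from rasters and default to one parcel per pixel.
    """
    import tifffile

    labels = np.asarray(tifffile.imread(label_path))
    if labels.ndim != 2:
        raise ValueError("label raster must be single-band")
    grid = labels.shape
    date_list = np.asarray(date_list, float)
    if len(band_paths) != len(date_list):
        raise ValueError("one raster per date is required")
    T = len(band_paths)
    refl = np.empty(grid + (T, len(BAND_NAMES)))
    for t, p in enumerate(band_paths):
        arr = np.asarray(tifffile.imread(p), float)
        if arr.ndim != 3:
            raise ValueError(f"{p} is not a multiband raster")
        if arr.shape[0] == len(BAND_NAMES) and arr.shape[-1] != len(BAND_NAMES):
            arr = np.moveaxis(arr, 0, -1)  # band-first layout
        if arr.shape[-1] != len(BAND_NAMES):
            raise ValueError(f"{p} has {arr.shape[-1]} bands; 12 expected")
        refl[:, :, t, :] = _nearest_resample(arr, grid)
    labels = labels.astype(int)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(int(labels.max()) + 1)]
    return LabeledScene(
        reflectance=np.clip(refl, 0.0, 1.0),
        labels=labels,
        parcel_ids=np.arange(labels.size).reshape(grid),
        band_names=BAND_NAMES,
        date_list=date_list,
        class_names=class_names,
    )
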