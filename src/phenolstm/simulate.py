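"""Synthetic labeled multispectral time-series scenes.

Generates the statistical structure a land-use time-series classifier
assumes: class-specific phenology curves, spectrally correlated bands, parcel
(block) spatial structure, and i.i.d. reflectance noise.  The generator is the
test bed for the whole pipeline: every downstream claim (classification
accuracy, predictor and date relevance, activation localization) is checked
against signal that was planted here on purpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import BAND_NAMES, PhenologyProfile, SceneConfig

__all__ = [
    "LabeledScene",
    "double_logistic_ndvi",
    "ndvi_to_reflectance",
    "generate_scene",
    "split_train_test",
]


@dataclass
class LabeledScene:
    """A spatial grid of labeled pixels with per-date 12-band reflectances.

    Attributes
    ----------
    reflectance
        ``(grid_height, grid_width, n_dates, 12)`` array in reflectance
        units, clipped to ``[0, 1]``.
    labels
        ``(grid_height, grid_width)`` integer class map (indices into
        ``class_names``).
    parcel_ids
        ``(grid_height, grid_width)`` integer map; pixels sharing a parcel
        share a label.
    band_names
        The 12 band names, in storage order.
    date_list
        Agronomic-year day numbers (day 0 = September 1), one per date.
    class_names
        Class label strings, index-aligned with ``labels``.
    """

    reflectance: np.ndarray
    labels: np.ndarray
    parcel_ids: np.ndarray
    band_names: tuple[str, ...]
    date_list: np.ndarray
    class_names: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_pixels(self) -> int:
        return int(self.labels.size)

    @property
    def n_dates(self) -> int:
        return int(len(self.date_list))


def double_logistic_ndvi(day, profile: PhenologyProfile):
    """Double-logistic phenology curve: NDVI as a function of day.

    The standard remote-sensing greenness model — a rising logistic at
    green-up minus a second logistic at senescence::

        ndvi(d) = base + amp * [ 1/(1+exp(-r_g (d - d_g)))
                               - 1/(1+exp(-r_s (d - d_s))) ]

    Vectorized over ``day``; returns values in ``[-1, 1]``.
    """
    day = np.asarray(day, float)
    up = 1.0 / (1.0 + np.exp(-profile.greenup_rate * (day - profile.greenup_day)))
    down = 1.0 / (1.0 + np.exp(-profile.senescence_rate * (day - profile.senescence_day)))
    out = profile.ndvi_base + profile.ndvi_amplitude * (up - down)
    return out if out.ndim else float(out)


def ndvi_to_reflectance(ndvi, profile: PhenologyProfile, rng=None):
    """Map NDVI value(s) to a 12-band reflectance vector.

    B4 (red) and B8 (NIR) are solved so that ``(B8-B4)/(B8+B4)`` equals
    ``ndvi`` exactly before noise, with ``B8 + B4`` fixed to the profile's
    ``band_sum``.  Every other band is an affine function of NDVI with the
    profile's class-specific coefficients — except bands outside
    ``informative_bands``, which receive class-independent constants and so
    carry no class signal.  If ``rng`` is given, i.i.d. Gaussian noise of sd
    ``band_noise_sd`` is added; the result is clipped to ``[0, 1]``.

    Parameters
    ----------
    ndvi
        Scalar or array of NDVI values in ``[-1, 1]``.
    rng
        Optional :class:`numpy.random.Generator`; omit for a noise-free
        deterministic vector.

    Returns
    -------
    ndarray with shape ``ndvi.shape + (12,)``.
    """
    ndvi = np.asarray(ndvi, float)
    if np.any(ndvi < -1.0) or np.any(ndvi > 1.0):
        raise ValueError("ndvi outside [-1, 1]")
    s = profile.band_sum
    out = np.empty(ndvi.shape + (len(BAND_NAMES),))
    for j, band in enumerate(BAND_NAMES):
        if band == "B8":
            out[..., j] = s * (1.0 + ndvi) / 2.0
        elif band == "B4":
            out[..., j] = s * (1.0 - ndvi) / 2.0
        else:
            icpt, slope = profile.band_affine[band]
            out[..., j] = icpt + slope * ndvi
    if rng is not None and profile.band_noise_sd > 0:
        out = out + rng.normal(0.0, profile.band_noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


def _assign_parcels(config: SceneConfig, rng: np.random.Generator):
    """Tile the grid into square parcels and assign one class per parcel.

    Parcels are apportioned to classes by largest remainder on
    ``class_proportions`` (every class with positive proportion gets at least
    one parcel), then shuffled spatially.
    """
    h, w, ps = config.grid_height, config.grid_width, config.parcel_size
    if h % ps or w % ps:
        raise ValueError(
            f"grid {h}x{w} not divisible by parcel_size {ps}"
        )
    n_parcels = (h // ps) * (w // ps)
    props = config.class_proportions
    n_classes = len(props)
    if (props > 0).sum() > n_parcels:
        raise ValueError(
            f"{int((props > 0).sum())} classes but only {n_parcels} parcels"
        )
    quota = props * n_parcels
    counts = np.floor(quota).astype(int)
    counts[(props > 0) & (counts == 0)] = 1
    while counts.sum() > n_parcels:  # floors + minimums may overshoot
        counts[np.argmax(counts)] -= 1
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder)
    i = 0
    while counts.sum() < n_parcels:
        counts[order[i % n_classes]] += 1
        i += 1
    parcel_class = np.repeat(np.arange(n_classes), counts)
    rng.shuffle(parcel_class)
    return parcel_class.reshape(h // ps, w // ps)


def generate_scene(config: SceneConfig) -> LabeledScene:
    """Generate a :class:`LabeledScene` from *config*, deterministic given
    ``config.seed``.

    Parcels tile the grid; each parcel is assigned a class by
    ``class_proportions``; each pixel's reflectance follows its class's
    double-logistic NDVI curve through :func:`ndvi_to_reflectance`, with
    independent Gaussian band noise per pixel/date/band.
    """
    rng = np.random.default_rng(config.seed)
    parcel_class = _assign_parcels(config, rng)
    ps = config.parcel_size
    labels = np.kron(parcel_class, np.ones((ps, ps), int))
    parcel_idx = np.arange(parcel_class.size).reshape(parcel_class.shape)
    parcel_ids = np.kron(parcel_idx, np.ones((ps, ps), int))

    h, w = labels.shape
    T = config.n_dates
    clean = np.empty((h, w, T, len(BAND_NAMES)))
    sd_map = np.empty((h, w))
    for k, profile in enumerate(config.profiles):
        mask = labels == k
        if not mask.any():
            continue
        curve = double_logistic_ndvi(config.date_list, profile)  # (T,)
        clean[mask] = ndvi_to_reflectance(curve, profile)  # (T, 12)
        sd_map[mask] = profile.band_noise_sd
    noise = rng.standard_normal((h, w, T, len(BAND_NAMES)))
    reflectance = np.clip(clean + noise * sd_map[:, :, None, None], 0.0, 1.0)
    return LabeledScene(
        reflectance=reflectance,
        labels=labels,
        parcel_ids=parcel_ids,
        band_names=BAND_NAMES,
        date_list=np.asarray(config.date_list, float),
        class_names=config.class_names,
    )


def split_train_test(
    scene: LabeledScene,
    train_fraction: float = 0.7,
    mode: str = "pixel",
    seed: int = 0,
):
    """Split pixel indices into disjoint, exhaustive train/test sets.

    ``mode="pixel"``: stratified by class — each class contributes
    ``round(train_fraction * n_class)`` training pixels.
    ``mode="parcel"``: whole parcels go to one side, stratified by the
    parcel's class; no parcel id appears in both sets.  A class owning a
    single parcel triggers a warning (it will be absent from one side).

    Returns
    -------
    (train_idx, test_idx)
        Flat (raveled) pixel index arrays, sorted ascending.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if mode not in ("pixel", "parcel"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    labels = scene.labels.ravel()
    train_parts, test_parts = [], []
    if mode == "pixel":
        for k in np.unique(labels):
            idx = np.flatnonzero(labels == k)
            rng.shuffle(idx)
            n_train = int(round(train_fraction * idx.size))
            train_parts.append(idx[:n_train])
            test_parts.append(idx[n_train:])
    else:
        parcels = scene.parcel_ids.ravel()
        parcel_label = {}
        for pid in np.unique(parcels):
            parcel_label[pid] = labels[parcels == pid][0]
        by_class: dict[int, list[int]] = {}
        for pid, k in parcel_label.items():
            by_class.setdefault(int(k), []).append(int(pid))
        for k, pids in sorted(by_class.items()):
            if len(pids) == 1:
                warnings.warn(
                    f"class {scene.class_names[k]!r} owns a single parcel; "
                    "it will be absent from one side of the split",
                    stacklevel=2,
                )
            pids = np.array(pids)
            rng.shuffle(pids)
            n_class = int((labels == k).sum())
            taken = 0
            cut = 0
            for pid in pids:
                if taken >= train_fraction * n_class:
                    break
                taken += int((parcels == pid).sum())
                cut += 1
            if len(pids) > 1:  # keep both sides non-empty for the class
                cut = min(max(cut, 1), len(pids) - 1)
            train_pids, test_pids = set(pids[:cut].tolist()), set(pids[cut:].tolist())
            train_parts.append(np.flatnonzero(np.isin(parcels, list(train_pids))))
            if test_pids:
                test_parts.append(np.flatnonzero(np.isin(parcels, list(test_pids))))
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    return train_idx, test_idx
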