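"""Added-noise permutation relevance and hidden-state interpretability.

Relevance of a predictor (or acquisition date) is measured by corrupting it
with Gaussian white noise N(0, σ²) — σ² set to a fraction (default 3%) of the
perturbed signal's amplitude — re-evaluating classification accuracy, and
taking the drop from the unperturbed baseline.  Drops are normalized to the
most relevant item.  Per-timestep probability evolution and hidden-unit
activation summaries expose how information flows through the network over
the agronomic year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureCube
from .network import NetworkModel, network_forward
from .training import predict_proba

__all__ = [
    "RelevanceResult",
    "ActivationSummary",
    "perturb",
    "relevance",
    "probability_evolution",
    "activation_summary",
]


@dataclass
class RelevanceResult:
    """Normalized relevance scores for the 14 predictors or the 30 dates.

    ``scores`` are accuracy drops divided by the largest drop, so the most
    relevant item scores exactly 1; negative drops are clipped to 0.  When no
    perturbation hurts accuracy, ``all_zero`` is set and scores are all 0.
    ``raw_accuracy_drops`` holds per-item, per-repeat drops in accuracy
    percentage points.
    """

    mode: str
    item_names: list[str]
    scores: np.ndarray
    raw_accuracy_drops: np.ndarray  # (n_items, n_repeats)
    baseline_accuracy: float
    n_repeats: int
    noise_fraction: float
    seed: int
    all_zero: bool = False

    def ranking(self) -> list[str]:
        """Item names sorted from most to least relevant."""
        return [self.item_names[i] for i in np.argsort(-self.scores, kind="stable")]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "item_names": self.item_names,
            "scores": self.scores.tolist(),
            "raw_accuracy_drops": self.raw_accuracy_drops.tolist(),
            "baseline_accuracy": self.baseline_accuracy,
            "n_repeats": self.n_repeats,
            "noise_fraction": self.noise_fraction,
            "seed": self.seed,
            "all_zero": self.all_zero,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class ActivationSummary:
    """Hidden-unit activation statistics of the last BiLSTM layer.

    ``heatmap`` is ``(2 * hidden_size, n_timesteps)`` mean activations over
    samples; ``mean_squared_by_date`` averages the squared activations over
    units and samples per timestep; ``per_class_curves`` holds the same
    series restricted to each class.
    """

    heatmap: np.ndarray
    mean_squared_by_date: np.ndarray
    per_class_curves: dict[str, np.ndarray] | None
    class_counts: dict[str, int] | None
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "heatmap": self.heatmap.tolist(),
            "mean_squared_by_date": self.mean_squared_by_date.tolist(),
            "per_class_curves": None if self.per_class_curves is None else {
                k: v.tolist() for k, v in self.per_class_curves.items()
            },
            "class_counts": self.class_counts,
            "n_samples": self.n_samples,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def perturb(
    cube: FeatureCube,
    mode: str,
    index: int,
    noise_fraction: float = 0.03,
    rng: np.random.Generator | None = None,
) -> FeatureCube:
    """Return a copy of *cube* with calibrated Gaussian noise on one target.

    ``mode="predictor"``: noise is added to feature ``index`` at *all*
    timesteps; the noise variance is ``noise_fraction`` times that feature's
    amplitude (max − min over all samples and timesteps).
    ``mode="date"``: noise is added to *all* features at timestep ``index``;
    each feature gets its own variance from its amplitude at that date.
    Untargeted entries are bit-identical to the input.  A zero-amplitude
    target is left untouched with a warning.
    """
    if mode not in ("predictor", "date"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    n_items = cube.n_features if mode == "predictor" else cube.n_timesteps
    if not 0 <= index < n_items:
        raise IndexError(f"{mode} index {index} out of range [0, {n_items})")
    if rng is None:
        rng = np.random.default_rng(0)
    values = cube.values.copy()
    if mode == "predictor":
        target = values[:, :, index]
        amplitude = float(target.max() - target.min())
        if amplitude == 0.0:
            warnings.warn(f"zero amplitude for predictor {index}; no-op", stacklevel=2)
        else:
            sigma = np.sqrt(noise_fraction * amplitude)
            values[:, :, index] = target + rng.normal(0.0, sigma, target.shape)
    else:
        target = values[:, index, :]  # (n_samples, n_features)
        amplitude = target.max(axis=0) - target.min(axis=0)  # per feature
        if np.all(amplitude == 0.0):
            warnings.warn(f"zero amplitude for date {index}; no-op", stacklevel=2)
        else:
            sigma = np.sqrt(noise_fraction * amplitude)
            values[:, index, :] = target + rng.normal(0.0, 1.0, target.shape) * sigma
    return FeatureCube(
        values=values,
        feature_names=cube.feature_names,
        sample_index=cube.sample_index,
        labels=cube.labels,
        class_names=cube.class_names,
        date_list=cube.date_list,
        mean=cube.mean,
        scale=cube.scale,
    )


def _accuracy(model: NetworkModel, values: np.ndarray, y: np.ndarray) -> float:
    probs = predict_proba(model, values)
    return float(100.0 * (probs.argmax(axis=1) == y).mean())


def relevance(
    model: NetworkModel,
    cube: FeatureCube,
    mode: str = "predictor",
    n_repeats: int = 10,
    noise_fraction: float = 0.03,
    seed: int = 0,
) -> RelevanceResult:
    """Added-noise permutation relevance of every predictor or date.

    The baseline overall accuracy is computed once; each item's accuracy drop
    is averaged over ``n_repeats`` independent noise draws, then the drops
    are normalized by the largest one (negatives clipped to 0 first).
    """
    if cube.labels is None:
        raise ValueError("relevance requires a labeled cube")
    if model.n_features is not None and cube.n_features != model.n_features:
        raise ValueError(
            f"cube has {cube.n_features} features; model expects {model.n_features}"
        )
    y = np.asarray(cube.labels, int)
    baseline = _accuracy(model, cube.values, y)
    n_items = cube.n_features if mode == "predictor" else cube.n_timesteps
    if mode == "predictor":
        item_names = list(cube.feature_names)
    elif cube.date_list is not None:
        item_names = [f"t{t:02d}_day{int(round(d))}" for t, d in enumerate(cube.date_list)]
    else:
        item_names = [f"t{t:02d}" for t in range(n_items)]
    rng = np.random.default_rng(seed)
    drops = np.empty((n_items, n_repeats))
    for item in range(n_items):
        for r in range(n_repeats):
            perturbed = perturb(cube, mode, item, noise_fraction, rng)
            drops[item, r] = baseline - _accuracy(model, perturbed.values, y)
    mean_drops = np.clip(drops.mean(axis=1), 0.0, None)
    top = mean_drops.max()
    if top <= 0.0:
        scores = np.zeros(n_items)
        all_zero = True
    else:
        scores = mean_drops / top
        all_zero = False
    return RelevanceResult(
        mode=mode,
        item_names=item_names,
        scores=scores,
        raw_accuracy_drops=drops,
        baseline_accuracy=baseline,
        n_repeats=n_repeats,
        noise_fraction=noise_fraction,
        seed=seed,
        all_zero=all_zero,
    )


def probability_evolution(
    model: NetworkModel, sequence: np.ndarray, method: str = "incremental"
) -> np.ndarray:
    """Per-timestep class-probability trajectory of one sample.

    ``sequence`` is ``(n_timesteps, n_features)`` — the full series is
    required.  Returns ``(n_timesteps, n_classes)``; rows sum to 1.

    ``method="incremental"`` (default) evaluates the network on the truncated
    series ``x_1..x_t`` for every t, i.e. the probability the classifier
    would assign having observed the year only up to that acquisition.  This
    is the trajectory that tracks phenology: an annual crop's probability
    stays low before its growing cycle and rises sharply once the cycle
    unfolds.  ``method="aligned"`` instead applies the softmax head to the
    aligned bidirectional output at each t; since the backward half has then
    already consumed the entire series, those trajectories are close to flat
    and mostly reflect the final decision.
    """
    sequence = np.asarray(sequence, float)
    if sequence.ndim != 2:
        raise ValueError("sequence must be (n_timesteps, n_features)")
    if model.n_timesteps is not None and sequence.shape[0] != model.n_timesteps:
        raise ValueError(
            f"sequence has {sequence.shape[0]} timesteps; the model expects "
            f"the full series of {model.n_timesteps}"
        )
    if method == "aligned":
        ts_probs, _, _ = network_forward(model, sequence[None], mode="eval")
        return ts_probs[0]
    if method != "incremental":
        raise ValueError(f"unknown method {method!r}")
    T = sequence.shape[0]
    out = np.empty((T, model.n_classes))
    for t in range(T):
        _, _, probs = network_forward(model, sequence[None, : t + 1], mode="eval")
        out[t] = probs[0]
    return out


def activation_summary(
    model: NetworkModel,
    cube: FeatureCube,
    by_class: bool = False,
    chunk_size: int = 2048,
) -> ActivationSummary:
    """Last-layer hidden-state activation statistics in eval mode.

    ``heatmap``: per-unit mean activation over samples for every timestep.
    ``mean_squared_by_date``: mean over units and samples of the squared
    activations, one value per date.  With ``by_class``, the same series is
    computed per class; the class curves, weighted by class proportions,
    recombine exactly to the pooled curve.
    """
    if cube.n_samples == 0:
        raise ValueError("empty sample set")
    if by_class and cube.labels is None:
        raise ValueError("by_class requires labels")
    n = cube.n_samples
    sum_h = None
    sum_sq_t = None
    per_class_sum: dict[int, np.ndarray] = {}
    per_class_n: dict[int, int] = {}
    for start in range(0, n, chunk_size):
        sel = slice(start, start + chunk_size)
        _, hidden, _ = network_forward(model, cube.values[sel], mode="eval")
        sq = hidden ** 2  # (b, T, 2H)
        if sum_h is None:
            sum_h = hidden.sum(axis=0)  # (T, 2H)
            sum_sq_t = sq.mean(axis=2).sum(axis=0)  # (T,)
        else:
            sum_h += hidden.sum(axis=0)
            sum_sq_t += sq.mean(axis=2).sum(axis=0)
        if by_class:
            y = np.asarray(cube.labels[sel], int)
            for k in np.unique(y):
                contrib = sq[y == k].mean(axis=2).sum(axis=0)
                per_class_sum[k] = per_class_sum.get(k, 0.0) + contrib
                per_class_n[k] = per_class_n.get(k, 0) + int((y == k).sum())
    heatmap = (sum_h / n).T  # (2H, T)
    mean_sq = sum_sq_t / n
    curves = None
    counts = None
    if by_class:
        names = cube.class_names or [f"class_{k}" for k in sorted(per_class_sum)]
        curves = {names[k]: per_class_sum[k] / per_class_n[k] for k in sorted(per_class_sum)}
        counts = {names[k]: per_class_n[k] for k in sorted(per_class_n)}
    return ActivationSummary(
        heatmap=heatmap,
        mean_squared_by_date=mean_sq,
        per_class_curves=curves,
        class_counts=counts,
        n_samples=n,
    )
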