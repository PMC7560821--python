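"""Training and evaluation of the BiLSTM land-use classifier.

Training minimizes categorical cross-entropy on the sequence-level softmax
probabilities with mini-batch Adam; gradients come from backpropagation
through time written against the same cached forward pass the network module
produces.  Evaluation reports overall accuracy, per-class precision / recall /
F-1 and the confusion matrix on a held-out set.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .features import FeatureCube
from .network import (
    LSTMParams,
    NetworkModel,
    init_network,
    lstm_backward_batch,
    network_forward,
)

__all__ = ["TrainingConfig", "MetricsReport", "train", "evaluate", "architecture_sweep"]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference architecture — two BiLSTM layers of 100
    hidden units per direction with 50% dropout — and a common optimization
    recipe: Adam at learning rate 1e-3, batch size 256, up to 50 epochs with
    early stopping (patience 8) on an internal 10% validation slice.
    """

    n_layers: int = 2
    hidden_size: int = 100
    dropout_rate: float = 0.5
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    early_stopping_patience: int = 8
    validation_fraction: float = 0.1
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_name!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_layers", "hidden_size", "dropout_rate", "epochs", "batch_size",
            "learning_rate", "optimizer_name", "early_stopping_patience",
            "validation_fraction", "class_weighting", "seed")}


def _param_refs(model: NetworkModel):
    """Flat list of (container, attribute_name) for every trainable array."""
    refs = []
    for fwd, bwd in model.layers:
        for p in (fwd, bwd):
            for name in LSTMParams.array_names():
                refs.append((p, name))
    refs.append((model, "head_W"))
    refs.append((model, "head_b"))
    return refs


def network_backward(model: NetworkModel, X: np.ndarray, dlogits: np.ndarray, cache):
    """Gradients of the sequence-level loss w.r.t. every model parameter.

    ``dlogits`` is dLoss/d(sequence logits), ``(B, n_classes)``; ``cache``
    comes from ``network_forward(..., return_cache=True)``.  Returns a flat
    gradient list aligned with :func:`_param_refs`.
    """
    H = model.hidden_size
    B, T, _ = X.shape
    d_head_W = dlogits.T @ cache["seq_repr"]
    d_head_b = dlogits.sum(axis=0)
    d_seq = dlogits @ model.head_W  # (B, 2H)

    d_out = np.zeros((B, T, 2 * H))
    d_out[:, -1, :H] = d_seq[:, :H]
    d_out[:, 0, H:] = d_seq[:, H:]

    layer_grads: list[tuple[dict, dict]] = [None] * model.n_layers  # type: ignore[list-item]
    for ell in range(model.n_layers - 1, -1, -1):
        mask = cache["dropout_masks"][ell]
        d_pre = d_out * mask if mask is not None else d_out
        X_l = cache["layer_inputs"][ell]
        cf, cb = cache["layer_caches"][ell]
        fwd, bwd = model.layers[ell]
        grads_f, dX_f = lstm_backward_batch(d_pre[..., :H], X_l, cf, fwd)
        grads_b, dX_b_rev = lstm_backward_batch(
            np.ascontiguousarray(d_pre[:, ::-1, H:]),
            np.ascontiguousarray(X_l[:, ::-1]),
            cb,
            bwd,
        )
        layer_grads[ell] = (grads_f, grads_b)
        d_out = dX_f + dX_b_rev[:, ::-1]

    flat: list[np.ndarray] = []
    for grads_f, grads_b in layer_grads:
        for g in (grads_f, grads_b):
            flat.extend(g[name] for name in LSTMParams.array_names())
    flat.append(d_head_W)
    flat.append(d_head_b)
    return flat


class _Adam:
    def __init__(self, refs, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.refs = refs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for o, n in refs]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in refs]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (obj, name), g, m, v in zip(self.refs, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            setattr(obj, name, getattr(obj, name) - update)


def _check_classes(cube: FeatureCube) -> int:
    if cube.labels is None:
        raise ValueError("training cube carries no labels")
    n_classes = len(cube.class_names) if cube.class_names else int(cube.labels.max()) + 1
    present = np.unique(cube.labels)
    missing = sorted(set(range(n_classes)) - set(present.tolist()))
    if missing:
        names = [cube.class_names[k] for k in missing] if cube.class_names else missing
        raise ValueError(f"configured class(es) absent from training data: {names}")
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes")
    return n_classes


def train(config: TrainingConfig, train_cube: FeatureCube):
    """Train a stacked BiLSTM on *train_cube*; deterministic given the seed.

    Returns ``(model, history)`` where ``history`` maps ``"train_loss"``,
    ``"train_accuracy"`` (and, with a validation slice, ``"val_loss"`` /
    ``"val_accuracy"``) to per-epoch lists.
    """
    n_classes = _check_classes(train_cube)
    rng = np.random.default_rng(config.seed)
    model = init_network(
        n_features=train_cube.n_features,
        n_classes=n_classes,
        class_names=train_cube.class_names,
        n_layers=config.n_layers,
        hidden_size=config.hidden_size,
        dropout_rate=config.dropout_rate,
        n_timesteps=train_cube.n_timesteps,
        seed=int(rng.integers(2 ** 31)),
    )
    model.training_config = config.to_dict()

    X = train_cube.values
    y = np.asarray(train_cube.labels, int)
    n = X.shape[0]
    order = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, fit_idx = order[:n_val], order[n_val:]
    if len(np.unique(y[fit_idx])) < n_classes:  # keep every class in the fit slice
        val_idx, fit_idx = order[:0], order
        n_val = 0

    if config.class_weighting:
        freq = np.bincount(y[fit_idx], minlength=n_classes).astype(float)
        w_class = freq.sum() / np.maximum(freq, 1.0) / n_classes
    else:
        w_class = np.ones(n_classes)

    refs = _param_refs(model)
    opt = _Adam(refs, config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "train_accuracy": []}
    if n_val:
        history["val_loss"] = []
        history["val_accuracy"] = []
    best_val = np.inf
    best_state = None
    patience_left = config.early_stopping_patience

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(fit_idx))
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, len(fit_idx), config.batch_size):
            sel = fit_idx[perm[start:start + config.batch_size]]
            Xb, yb = X[sel], y[sel]
            _, _, probs, cache = network_forward(
                model, Xb, mode="train", rng=rng, return_cache=True
            )
            p_true = probs[np.arange(len(sel)), yb]
            w = w_class[yb]
            loss = -np.mean(w * np.log(np.maximum(p_true, 1e-300)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; "
                    "reduce the learning rate or check the inputs"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(sel)), yb] = 1.0
            dlogits = (probs - onehot) * w[:, None] / len(sel)
            grads = network_backward(model, Xb, dlogits, cache)
            opt.step(grads)
            epoch_loss += loss * len(sel)
            epoch_correct += int((probs.argmax(axis=1) == yb).sum())
        history["train_loss"].append(epoch_loss / len(fit_idx))
        history["train_accuracy"].append(epoch_correct / len(fit_idx))

        if n_val:
            probs_v = predict_proba(model, X[val_idx])
            loss_v = -np.mean(np.log(np.maximum(probs_v[np.arange(n_val), y[val_idx]], 1e-300)))
            acc_v = float((probs_v.argmax(axis=1) == y[val_idx]).mean())
            history["val_loss"].append(float(loss_v))
            history["val_accuracy"].append(acc_v)
            if loss_v < best_val - 1e-6:
                best_val = loss_v
                best_state = [getattr(o, a).copy() for o, a in refs]
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_state is not None:
        for (obj, name), arr in zip(refs, best_state):
            setattr(obj, name, arr)
    return model, history


def predict_proba(
    model: NetworkModel, X: np.ndarray, chunk_size: int = 2048
) -> np.ndarray:
    """Sequence-level class probabilities in eval mode, chunked over samples."""
    out = np.empty((X.shape[0], model.n_classes))
    for start in range(0, X.shape[0], chunk_size):
        _, _, probs = network_forward(model, X[start:start + chunk_size], mode="eval")
        out[start:start + chunk_size] = probs
    return out


@dataclass
class MetricsReport:
    """Overall accuracy, per-class precision/recall/F-1 (all in %), and the
    confusion matrix (rows = reference class, columns = prediction)."""

    overall_accuracy: float
    per_class: dict[str, dict[str, float]]
    confusion_matrix: np.ndarray
    class_names: list[str]
    n_test: int
    n_train: int | None = None
    split_mode: str | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": self.per_class,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_names": self.class_names,
            "n_test": self.n_test,
            "n_train": self.n_train,
            "split_mode": self.split_mode,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_table(self) -> pd.DataFrame:
        """Per-class metrics as a table (class, precision %, recall %, F-1 %)."""
        rows = [
            {"class": name, "precision": m["precision"],
             "recall": m["recall"], "f1": m["f1"]}
            for name, m in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def evaluate(
    model: NetworkModel,
    test_cube: FeatureCube,
    n_train: int | None = None,
    split_mode: str | None = None,
    seed: int | None = None,
) -> MetricsReport:
    """Evaluate on a labeled cube: predictions are the argmax of the
    sequence-level probabilities (ties broken toward the lowest class index)."""
    if test_cube.labels is None:
        raise ValueError("test cube carries no labels")
    if test_cube.n_samples == 0:
        raise ValueError("test set is empty")
    y = np.asarray(test_cube.labels, int)
    if y.max() >= model.n_classes:
        raise ValueError(
            f"test labels reference class {y.max()} but model has "
            f"{model.n_classes} classes"
        )
    probs = predict_proba(model, test_cube.values)
    pred = probs.argmax(axis=1)
    labels = np.arange(model.n_classes)
    cm = _sk_confusion(y, pred, labels=labels)
    prec, rec, f1, _ = _sk_prfs(y, pred, labels=labels, zero_division=0)
    per_class = {
        name: {
            "precision": float(100.0 * prec[k]),
            "recall": float(100.0 * rec[k]),
            "f1": float(100.0 * f1[k]),
        }
        for k, name in enumerate(model.class_names)
    }
    return MetricsReport(
        overall_accuracy=float(100.0 * np.trace(cm) / cm.sum()),
        per_class=per_class,
        confusion_matrix=cm,
        class_names=list(model.class_names),
        n_test=int(len(y)),
        n_train=n_train,
        split_mode=split_mode,
        seed=seed,
    )


def architecture_sweep(
    configs: list[TrainingConfig],
    train_cube: FeatureCube,
    test_cube: FeatureCube,
):
    """Train and evaluate each configuration on identical data.

    Returns ``(table, runs)``: a comparison DataFrame (one row per variant,
    with overall accuracy and wall time) and the per-run records including
    loss histories; failures are recorded and the sweep continues.
    """
    if not configs:
        raise ValueError("at least one configuration is required")
    runs = []
    rows = []
    for cfg in configs:
        rec: dict = {"config": cfg}
        t0 = time.perf_counter()
        try:
            model, history = train(cfg, train_cube)
            report = evaluate(
                model, test_cube, n_train=train_cube.n_samples, seed=cfg.seed
            )
            rec.update(model=model, history=history, report=report, error=None)
            rows.append({
                "n_layers": cfg.n_layers,
                "hidden_size": cfg.hidden_size,
                "overall_accuracy": report.overall_accuracy,
                "n_train": train_cube.n_samples,
                "n_test": test_cube.n_samples,
                "epochs_run": len(history["train_loss"]),
                "wall_time_s": time.perf_counter() - t0,
            })
        except Exception as exc:  # recorded, sweep continues
            rec.update(model=None, history=None, report=None, error=str(exc))
            rows.append({
                "n_layers": cfg.n_layers,
                "hidden_size": cfg.hidden_size,
                "overall_accuracy": np.nan,
                "n_train": train_cube.n_samples,
                "n_test": test_cube.n_samples,
                "epochs_run": 0,
                "wall_time_s": time.perf_counter() - t0,
            })
        runs.append(rec)
    return pd.DataFrame(rows), runs
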