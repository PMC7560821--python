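"""Stacked bidirectional LSTM classification network.

The LSTM unit follows the classic gate formulation: a candidate memory
modulated by tanh, input/forget/output gates modulated by the logistic
function, a memory cell updated as ``c_t = i ⊙ c̃ + f ⊙ c_{t-1}``, and a
hidden state ``h_t = o ⊙ tanh(c_t)``.  A bidirectional layer runs one LSTM
forward over the sequence and one backward, concatenating their aligned
outputs per timestep.  Layers are stacked (default two, 100 hidden units per
direction) with inverted dropout on each layer's output in training mode, and
a fully-connected softmax head maps the sequence-level representation — the
concatenation of each direction's final state, so both halves have consumed
the full series — to class probabilities.  The same head applied to the
aligned per-timestep outputs yields the per-timestep probability evolution.

Everything is plain NumPy; forward passes cache the gate activations so the
training module can backpropagate through time.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMParams",
    "NetworkModel",
    "lstm_step",
    "bilstm_layer",
    "network_forward",
    "init_network",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def _sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Weights of one LSTM direction: input weights ``W_*`` (hidden x input),
    recurrent weights ``U_*`` (hidden x hidden) and biases ``b_*`` for the
    candidate (c), input (i), forget (f) and output (o) gates."""

    W_c: np.ndarray
    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    U_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    b_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H, D = self.W_c.shape
        for name in ("W_c", "W_i", "W_f", "W_o"):
            if getattr(self, name).shape != (H, D):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {(H, D)}")
        for name in ("U_c", "U_i", "U_f", "U_o"):
            if getattr(self, name).shape != (H, H):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {(H, H)}")
        for name in ("b_c", "b_i", "b_f", "b_o"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {(H,)}")
        for name in self.array_names():
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite entries in {name}")

    @staticmethod
    def array_names() -> tuple[str, ...]:
        return ("W_c", "W_i", "W_f", "W_o", "U_c", "U_i", "U_f", "U_o",
                "b_c", "b_i", "b_f", "b_o")

    @property
    def hidden_size(self) -> int:
        return self.W_c.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_c.shape[1]

    # stacked (4H x D) views in gate order c, i, f, o — used by the fast path
    def stacked(self):
        W = np.concatenate([self.W_c, self.W_i, self.W_f, self.W_o], axis=0)
        U = np.concatenate([self.U_c, self.U_i, self.U_f, self.U_o], axis=0)
        b = np.concatenate([self.b_c, self.b_i, self.b_f, self.b_o])
        return W, U, b


def lstm_step(x_t, h_prev, c_prev, params: LSTMParams):
    """One LSTM timestep on a single input vector.

    Returns ``(h_t, c_t)`` where::

        c̃ = tanh(W_c x + U_c h_prev + b_c)
        i  = σ(W_i x + U_i h_prev + b_i)
        f  = σ(W_f x + U_f h_prev + b_f)
        c_t = i ⊙ c̃ + f ⊙ c_prev
        o  = σ(W_o x + U_o h_prev + b_o)
        h_t = o ⊙ tanh(c_t)
    """
    x_t = np.asarray(x_t, float)
    h_prev = np.asarray(h_prev, float)
    c_prev = np.asarray(c_prev, float)
    if x_t.shape != (params.input_size,):
        raise ValueError(f"x_t shape {x_t.shape} != ({params.input_size},)")
    if h_prev.shape != (params.hidden_size,):
        raise ValueError(f"h_prev shape {h_prev.shape} != ({params.hidden_size},)")
    if c_prev.shape != (params.hidden_size,):
        raise ValueError(f"c_prev shape {c_prev.shape} != ({params.hidden_size},)")
    c_tilde = np.tanh(params.W_c @ x_t + params.U_c @ h_prev + params.b_c)
    i = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    f = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    c_t = i * c_tilde + f * c_prev
    o = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def lstm_forward_batch(X: np.ndarray, params: LSTMParams, return_cache: bool = False):
    """Run one LSTM direction over a batch of sequences.

    ``X`` is ``(B, T, D)``; returns hidden states ``(B, T, H)`` and, if
    requested, the per-timestep gate cache needed for backpropagation.
    """
    B, T, D = X.shape
    H = params.hidden_size
    W, U, b = params.stacked()
    # project all inputs at once: (B, T, 4H)
    pre_x = X.reshape(B * T, D) @ W.T
    pre_x = pre_x.reshape(B, T, 4 * H) + b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    cache = [] if return_cache else None
    for t in range(T):
        a = pre_x[:, t, :] + h @ U.T
        c_tilde = np.tanh(a[:, :H])
        i = _sigmoid(a[:, H:2 * H])
        f = _sigmoid(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_new = i * c_tilde + f * c
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        if return_cache:
            cache.append((h, c, c_tilde, i, f, o, tanh_c))
        h, c = h_new, c_new
        Hs[:, t, :] = h
    return (Hs, cache) if return_cache else Hs


def lstm_backward_batch(dH: np.ndarray, X: np.ndarray, cache, params: LSTMParams):
    """Backpropagate through one LSTM direction.

    ``dH`` is the loss gradient w.r.t. every hidden state, ``(B, T, H)``.
    Returns ``(grads, dX)`` where ``grads`` maps parameter-array names to
    gradients and ``dX`` is ``(B, T, D)``.
    """
    B, T, D = X.shape
    H = params.hidden_size
    W, U, _ = params.stacked()
    dW = np.zeros((4 * H, D))
    dU = np.zeros((4 * H, H))
    db = np.zeros(4 * H)
    dX = np.empty((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, c_tilde, i, f, o, tanh_c = cache[t]
        dh = dH[:, t, :] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
        di = dc * c_tilde
        dct = dc * i
        df = dc * c_prev
        dc_next = dc * f
        da = np.concatenate(
            [
                dct * (1.0 - c_tilde ** 2),
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
            ],
            axis=1,
        )  # (B, 4H)
        dW += da.T @ X[:, t, :]
        dU += da.T @ h_prev
        db += da.sum(axis=0)
        dh_next = da @ U
        dX[:, t, :] = da @ W
    grads = {
        "W_c": dW[:H], "W_i": dW[H:2 * H], "W_f": dW[2 * H:3 * H], "W_o": dW[3 * H:],
        "U_c": dU[:H], "U_i": dU[H:2 * H], "U_f": dU[2 * H:3 * H], "U_o": dU[3 * H:],
        "b_c": db[:H], "b_i": db[H:2 * H], "b_f": db[2 * H:3 * H], "b_o": db[3 * H:],
    }
    return grads, dX


def bilstm_layer(sequence: np.ndarray, fwd: LSTMParams, bwd: LSTMParams) -> np.ndarray:
    """One bidirectional layer on a single ``(T, input_size)`` sequence.

    The forward LSTM iterates t = 1..T, the backward LSTM iterates the
    reversed sequence, both from zero initial states; the backward states are
    re-reversed so that the output at t is ``[h_t^fwd ; h_t^bwd]``,
    shape ``(T, 2 * hidden_size)``.
    """
    sequence = np.asarray(sequence, float)
    if sequence.ndim != 2 or sequence.shape[0] < 1:
        raise ValueError("sequence must be (T >= 1, input_size)")
    X = sequence[None]
    Hf = lstm_forward_batch(X, fwd)
    Hb = lstm_forward_batch(X[:, ::-1], bwd)[:, ::-1]
    return np.concatenate([Hf, Hb], axis=2)[0]


@dataclass
class NetworkModel:
    """Stacked BiLSTM classifier.

    ``layers`` holds per layer a ``(forward, backward)`` pair of
    :class:`LSTMParams`; layer ℓ>1 consumes the ``2 * hidden_size`` output of
    layer ℓ−1.  ``head_W``/``head_b`` map the ``2 * hidden_size`` sequence
    representation to class logits.
    """

    layers: list[tuple[LSTMParams, LSTMParams]]
    head_W: np.ndarray
    head_b: np.ndarray
    class_names: list[str]
    dropout_rate: float = 0.5
    n_features: int | None = None
    n_timesteps: int | None = None
    training_config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.layers) <= 4:
            raise ValueError("n_layers must be between 1 and 4")
        H = self.layers[0][0].hidden_size
        for ell, (f, b) in enumerate(self.layers):
            if f.hidden_size != H or b.hidden_size != H:
                raise ValueError("all layers must share hidden_size")
            expected = self.n_features if ell == 0 else 2 * H
            if self.n_features is not None or ell > 0:
                if expected is not None and f.input_size != expected:
                    raise ValueError(
                        f"layer {ell} input size {f.input_size} != {expected}"
                    )
            if f.input_size != b.input_size:
                raise ValueError(f"layer {ell} directions disagree on input size")
        if self.head_W.shape[1] != 2 * H:
            raise ValueError("head_W must map 2*hidden_size to classes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def hidden_size(self) -> int:
        return self.layers[0][0].hidden_size

    @property
    def n_classes(self) -> int:
        return self.head_W.shape[0]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def network_forward(
    model: NetworkModel,
    sequence_batch: np.ndarray,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Full forward pass of the stacked BiLSTM network.

    Parameters
    ----------
    sequence_batch
        ``(B, T, n_features)`` standardized predictor sequences.
    mode
        ``"train"`` applies inverted dropout (rate ``model.dropout_rate``)
        to every BiLSTM layer's output and requires ``rng``; ``"eval"`` is
        deterministic.

    Returns
    -------
    (timestep_probs, last_hidden, seq_probs)
        ``timestep_probs``: ``(B, T, n_classes)`` — the softmax head applied
        to the last layer's aligned output at every timestep.
        ``last_hidden``: ``(B, T, 2 * hidden_size)`` last-layer outputs
        (pre-dropout), for activation analysis.
        ``seq_probs``: ``(B, n_classes)`` from the concatenation of each
        direction's final state (forward after x_T, backward after x_1).
    """
    X = np.asarray(sequence_batch, float)
    if X.ndim != 3:
        raise ValueError("sequence_batch must be (B, T, n_features)")
    if model.n_features is not None and X.shape[2] != model.n_features:
        raise ValueError(
            f"batch has {X.shape[2]} features; model expects {model.n_features}"
        )
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "train" and model.dropout_rate > 0 and rng is None:
        raise ValueError("train mode with dropout requires rng")

    B, T, _ = X.shape
    H = model.hidden_size
    cache = {"layer_caches": [], "dropout_masks": [], "layer_inputs": []} if return_cache else None
    cur = X
    last_hidden = None
    for ell, (fwd, bwd) in enumerate(model.layers):
        if return_cache:
            cache["layer_inputs"].append(cur)
            Hf, cf = lstm_forward_batch(cur, fwd, return_cache=True)
            Hb_rev, cb = lstm_forward_batch(cur[:, ::-1], bwd, return_cache=True)
        else:
            Hf = lstm_forward_batch(cur, fwd)
            Hb_rev = lstm_forward_batch(cur[:, ::-1], bwd)
        Hb = Hb_rev[:, ::-1]
        out = np.concatenate([Hf, Hb], axis=2)  # (B, T, 2H)
        if not np.isfinite(out).all():
            raise FloatingPointError(f"non-finite activations in layer {ell}")
        if ell == model.n_layers - 1:
            last_hidden = out
        if mode == "train" and model.dropout_rate > 0:
            mask = (rng.random(out.shape) >= model.dropout_rate) / (1.0 - model.dropout_rate)
            out = out * mask
        else:
            mask = None
        if return_cache:
            cache["layer_caches"].append((cf, cb))
            cache["dropout_masks"].append(mask)
        cur = out

    # sequence-level representation: forward final state ; backward final state
    seq_repr = np.concatenate([cur[:, -1, :H], cur[:, 0, H:]], axis=1)
    seq_logits = seq_repr @ model.head_W.T + model.head_b
    seq_probs = _softmax(seq_logits)
    ts_logits = cur @ model.head_W.T + model.head_b
    timestep_probs = _softmax(ts_logits)
    if return_cache:
        cache["seq_repr"] = seq_repr
        cache["seq_probs"] = seq_probs
        cache["final_dropped"] = cur
        return timestep_probs, last_hidden, seq_probs, cache
    return timestep_probs, last_hidden, seq_probs


def init_network(
    n_features: int,
    n_classes: int,
    class_names: list[str] | None = None,
    n_layers: int = 2,
    hidden_size: int = 100,
    dropout_rate: float = 0.5,
    n_timesteps: int | None = None,
    seed: int = 0,
) -> NetworkModel:
    """Seeded weight initialization: all matrices uniform in
    ``±1/sqrt(hidden_size)``; forget-gate bias 1, other biases 0."""
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(hidden_size)

    def make_params(input_size: int) -> LSTMParams:
        arrs = {}
        for name in ("W_c", "W_i", "W_f", "W_o"):
            arrs[name] = rng.uniform(-bound, bound, (hidden_size, input_size))
        for name in ("U_c", "U_i", "U_f", "U_o"):
            arrs[name] = rng.uniform(-bound, bound, (hidden_size, hidden_size))
        for name in ("b_c", "b_i", "b_o"):
            arrs[name] = np.zeros(hidden_size)
        arrs["b_f"] = np.ones(hidden_size)
        return LSTMParams(**arrs)

    layers = []
    for ell in range(n_layers):
        d = n_features if ell == 0 else 2 * hidden_size
        layers.append((make_params(d), make_params(d)))
    head_W = rng.uniform(-bound, bound, (n_classes, 2 * hidden_size))
    head_b = np.zeros(n_classes)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(n_classes)]
    return NetworkModel(
        layers=layers,
        head_W=head_W,
        head_b=head_b,
        class_names=list(class_names),
        dropout_rate=dropout_rate,
        n_features=n_features,
        n_timesteps=n_timesteps,
        seed=seed,
    )


class ModelFormatError(RuntimeError):
    """Raised when a model file is corrupted or has an unknown format version."""


def save_model(model: NetworkModel, path) -> None:
    """Serialize to a single ``.npz`` container with a format-version field."""
    arrays = {}
    for ell, (f, b) in enumerate(model.layers):
        for name in LSTMParams.array_names():
            arrays[f"layer{ell}_fwd_{name}"] = getattr(f, name)
            arrays[f"layer{ell}_bwd_{name}"] = getattr(b, name)
    arrays["head_W"] = model.head_W
    arrays["head_b"] = model.head_b
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_layers": model.n_layers,
        "hidden_size": model.hidden_size,
        "dropout_rate": model.dropout_rate,
        "class_names": model.class_names,
        "n_features": model.n_features,
        "n_timesteps": model.n_timesteps,
        "training_config": model.training_config,
        "seed": model.seed,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> NetworkModel:
    """Load a model saved by :func:`save_model`; lossless round-trip."""
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, io.UnsupportedOperation, EOFError,
            zipfile.BadZipFile) as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if "meta_json" not in arrays:
        raise ModelFormatError(f"{path} is not a network model file")
    meta = json.loads(arrays["meta_json"].tobytes().decode())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {meta.get('format_version')}"
        )
    layers = []
    try:
        for ell in range(meta["n_layers"]):
            f = LSTMParams(**{n: arrays[f"layer{ell}_fwd_{n}"] for n in LSTMParams.array_names()})
            b = LSTMParams(**{n: arrays[f"layer{ell}_bwd_{n}"] for n in LSTMParams.array_names()})
            layers.append((f, b))
        model = NetworkModel(
            layers=layers,
            head_W=arrays["head_W"],
            head_b=arrays["head_b"],
            class_names=list(meta["class_names"]),
            dropout_rate=float(meta["dropout_rate"]),
            n_features=meta["n_features"],
            n_timesteps=meta["n_timesteps"],
            training_config=meta.get("training_config", {}),
            seed=meta.get("seed"),
        )
    except KeyError as exc:
        raise ModelFormatError(f"model file {path} is missing {exc}") from exc
    return model
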