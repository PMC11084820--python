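"""The NS classifier: bidirectional GRU + multi-head attention + softmax.

The network consumes the pooled 1 x 1280 sequence embedding ``x`` as a
single-timestep sequence, passes it through a bidirectional GRU (128
hidden units per direction, so the concatenated output has width
H = 256), a 32-head self-attention layer over the GRU output, and a
fully connected softmax layer over the 10 NS classes:

    H_gru       = f_gru(x)
    H_attention = f_attention(H_gru)
    Y           = f_fc(H_attention)

trained by minimising the multi-class cross-entropy
H(p, q) = -sum_x p(x) log q(x) with Adam at learning rate 0.001,
batch size 1024, dropout 0.5, 200 epochs.

The implementation is pure numpy with hand-derived gradients (verified
against finite differences in the test suite). The forward pass is
written for a general timestep axis, so the same code also supports the
optional mode that runs the GRU over per-residue embeddings and pools
after attention; the default, single-timestep path feeds the pooled
vector directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from deepsub.embedding import EmbeddingMatrix, PooledEmbedding

#: NS labels in model-index order; ascending, so that argmax tie-breaking
#: toward the first index resolves toward the smaller NS label.
NS_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12)


@dataclass
class DeepSubConfig:
    """Hyperparameters of the classifier head.

    ``gru_hidden`` counts units per direction; the bidirectional
    concatenation therefore has width ``2 * gru_hidden``, which must be
    divisible by ``attention_heads``.
    """

    input_width: int = 1280
    gru_hidden: int = 128
    attention_heads: int = 32
    n_classes: int = 10
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_width", "gru_hidden", "attention_heads", "n_classes",
                     "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if (2 * self.gru_hidden) % self.attention_heads != 0:
            raise ValueError("2 * gru_hidden must be divisible by attention_heads")

    @property
    def hidden_width(self) -> int:
        return 2 * self.gru_hidden


@dataclass
class ClassProbabilities:
    """Softmax output Y over the NS classes."""

    Y: np.ndarray
    label_map: tuple[int, ...] = NS_LABELS

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64).reshape(-1)
        if len(self.Y) != len(self.label_map):
            raise ValueError("probability vector length does not match the label map")
        if np.any(self.Y < 0) or abs(self.Y.sum() - 1.0) > 1e-6:
            raise ValueError("Y is not a valid probability vector")

    @property
    def label(self) -> int:
        """Argmax label; ties resolve toward the smaller NS label."""
        return self.label_map[int(np.argmax(self.Y))]


@dataclass
class TrainedModel:
    params: dict[str, np.ndarray]
    config: DeepSubConfig
    label_map: tuple[int, ...] = NS_LABELS
    history: list[float] = field(default_factory=list)

    SCHEMA_VERSION = 1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: DeepSubConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    D, H, A = config.input_width, config.gru_hidden, config.hidden_width
    p: dict[str, np.ndarray] = {}
    for d in ("f", "b"):  # forward / backward direction
        for gate in ("z", "r", "h"):
            p[f"W{gate}_{d}"] = _glorot(rng, D, H)
            p[f"U{gate}_{d}"] = _glorot(rng, H, H)
            p[f"b{gate}_{d}"] = np.zeros(H)
    for proj in ("q", "k", "v", "o"):
        p[f"W{proj}"] = _glorot(rng, A, A)
        p[f"b{proj}"] = np.zeros(A)
    p["Wf"] = _glorot(rng, A, config.n_classes)
    p["bf"] = np.zeros(config.n_classes)
    return p


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _gru_direction_forward(X, Wz, Uz, bz, Wr, Ur, br, Wh, Uh, bh):
    """One GRU direction over X (B, T, D); Cho update
    h_t = (1 - z_t) h_{t-1} + z_t c_t with h_0 = 0."""
    B, T, _ = X.shape
    H = bz.shape[0]
    h = np.zeros((B, H))
    outs = np.empty((B, T, H))
    steps = []
    for t in range(T):
        x = X[:, t]
        z = _sigmoid(x @ Wz + h @ Uz + bz)
        r = _sigmoid(x @ Wr + h @ Ur + br)
        c = np.tanh(x @ Wh + (r * h) @ Uh + bh)
        h_new = (1.0 - z) * h + z * c
        steps.append((x, h, z, r, c))
        h = h_new
        outs[:, t] = h
    return outs, steps


def _gru_direction_backward(dOuts, steps, Wz, Uz, Wr, Ur, Wh, Uh):
    B, T, H = dOuts.shape
    D = steps[0][0].shape[1]
    g = {k: 0.0 for k in ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")}
    dX = np.empty((B, T, D))
    dh = np.zeros((B, H))
    for t in reversed(range(T)):
        x, h_prev, z, r, c = steps[t]
        dht = dOuts[:, t] + dh
        dz = dht * (c - h_prev)
        dc = dht * z
        dh_prev = dht * (1.0 - z)
        dc_pre = dc * (1.0 - c * c)
        g["Wh"] = g["Wh"] + x.T @ dc_pre
        g["Uh"] = g["Uh"] + (r * h_prev).T @ dc_pre
        g["bh"] = g["bh"] + dc_pre.sum(axis=0)
        drh = dc_pre @ Uh.T
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        g["Wz"] = g["Wz"] + x.T @ dz_pre
        g["Uz"] = g["Uz"] + h_prev.T @ dz_pre
        g["bz"] = g["bz"] + dz_pre.sum(axis=0)
        g["Wr"] = g["Wr"] + x.T @ dr_pre
        g["Ur"] = g["Ur"] + h_prev.T @ dr_pre
        g["br"] = g["br"] + dr_pre.sum(axis=0)
        dX[:, t] = dz_pre @ Wz.T + dr_pre @ Wr.T + dc_pre @ Wh.T
        dh = dh_prev + dz_pre @ Uz.T + dr_pre @ Ur.T
    return dX, g


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    B, T, A = x.shape
    return x.reshape(B, T, n_heads, A // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, nh, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, nh * dk)


def forward_pass(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    config: DeepSubConfig,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass on a batch X of shape (B, T, D).

    Returns (probs (B, C), cache). Dropout is active only when a
    ``dropout_rng`` is supplied (training mode); at inference the
    expected activations are used (inverted dropout).
    """
    if X.ndim != 3 or X.shape[2] != config.input_width:
        raise ValueError(
            f"input of shape {X.shape} does not match (B, T, {config.input_width})"
        )
    cache: dict = {"X": X}
    p = params

    out_f, steps_f = _gru_direction_forward(
        X, p["Wz_f"], p["Uz_f"], p["bz_f"], p["Wr_f"], p["Ur_f"], p["br_f"],
        p["Wh_f"], p["Uh_f"], p["bh_f"])
    Xrev = X[:, ::-1]
    out_b_rev, steps_b = _gru_direction_forward(
        Xrev, p["Wz_b"], p["Uz_b"], p["bz_b"], p["Wr_b"], p["Ur_b"], p["br_b"],
        p["Wh_b"], p["Uh_b"], p["bh_b"])
    out_b = out_b_rev[:, ::-1]
    O = np.concatenate([out_f, out_b], axis=-1)  # (B, T, A)
    cache.update(steps_f=steps_f, steps_b=steps_b)

    keep = 1.0 - config.dropout
    if dropout_rng is not None and config.dropout > 0:
        mask1 = (dropout_rng.random(O.shape) < keep) / keep
    else:
        mask1 = None
    O_d = O * mask1 if mask1 is not None else O
    cache.update(O=O, mask1=mask1, O_d=O_d)

    nh = config.attention_heads
    dk = config.hidden_width // nh
    Q = _split_heads(O_d @ p["Wq"] + p["bq"], nh)
    K = _split_heads(O_d @ p["Wk"] + p["bk"], nh)
    V = _split_heads(O_d @ p["Wv"] + p["bv"], nh)
    scale = 1.0 / np.sqrt(dk)
    S = np.einsum("bhtd,bhsd->bhts", Q, K) * scale
    P = _softmax(S, axis=-1)
    Ctx = np.einsum("bhts,bhsd->bhtd", P, V)
    Ctx_m = _merge_heads(Ctx)
    att = Ctx_m @ p["Wo"] + p["bo"]  # (B, T, A)
    cache.update(Q=Q, K=K, V=V, P=P, Ctx_m=Ctx_m, scale=scale, nh=nh)

    M = att.mean(axis=1)  # pool the timestep axis (identity for T = 1)
    if dropout_rng is not None and config.dropout > 0:
        mask2 = (dropout_rng.random(M.shape) < keep) / keep
    else:
        mask2 = None
    M_d = M * mask2 if mask2 is not None else M
    cache.update(mask2=mask2, M_d=M_d, T=X.shape[1])

    logits = M_d @ p["Wf"] + p["bf"]
    probs = _softmax(logits, axis=-1)
    cache["probs"] = probs
    return probs, cache


def backward_pass(
    params: dict[str, np.ndarray],
    cache: dict,
    y_onehot: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy loss w.r.t. every parameter."""
    p = params
    probs = cache["probs"]
    B = probs.shape[0]
    g: dict[str, np.ndarray] = {}

    dlogits = (probs - y_onehot) / B  # softmax + cross-entropy fused
    g["Wf"] = cache["M_d"].T @ dlogits
    g["bf"] = dlogits.sum(axis=0)
    dM = dlogits @ p["Wf"].T
    if cache["mask2"] is not None:
        dM = dM * cache["mask2"]
    T = cache["T"]
    datt = np.repeat(dM[:, None, :], T, axis=1) / T  # undo mean pool

    # attention output projection
    Bsz, _, A = datt.shape
    datt_m = datt.reshape(-1, A)
    g["Wo"] = cache["Ctx_m"].reshape(-1, A).T @ datt_m
    g["bo"] = datt_m.sum(axis=0)
    dCtx_m = (datt_m @ p["Wo"].T).reshape(Bsz, T, A)
    dCtx = _split_heads(dCtx_m, cache["nh"])

    P, Q, K, V, scale = cache["P"], cache["Q"], cache["K"], cache["V"], cache["scale"]
    dP = np.einsum("bhtd,bhsd->bhts", dCtx, V)
    dV = np.einsum("bhts,bhtd->bhsd", P, dCtx)
    dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
    dQ = np.einsum("bhts,bhsd->bhtd", dS, K) * scale
    dK = np.einsum("bhts,bhtd->bhsd", dS, Q) * scale

    O_d = cache["O_d"]
    O_m = O_d.reshape(-1, A)
    dO = np.zeros_like(O_d)
    for name, dproj in (("q", dQ), ("k", dK), ("v", dV)):
        dproj_m = _merge_heads(dproj).reshape(-1, A)
        g[f"W{name}"] = O_m.T @ dproj_m
        g[f"b{name}"] = dproj_m.sum(axis=0)
        dO += (dproj_m @ p[f"W{name}"].T).reshape(Bsz, T, A)

    if cache["mask1"] is not None:
        dO = dO * cache["mask1"]

    H = A // 2
    dX_f, g_f = _gru_direction_backward(
        dO[..., :H], cache["steps_f"],
        p["Wz_f"], p["Uz_f"], p["Wr_f"], p["Ur_f"], p["Wh_f"], p["Uh_f"])
    dX_b, g_b = _gru_direction_backward(
        dO[..., H:][:, ::-1], cache["steps_b"],
        p["Wz_b"], p["Uz_b"], p["Wr_b"], p["Ur_b"], p["Wh_b"], p["Uh_b"])
    for k, v in g_f.items():
        g[f"{k}_f"] = v
    for k, v in g_b.items():
        g[f"{k}_b"] = v
    g["_dX"] = dX_f + dX_b[:, ::-1]
    return g


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def cross_entropy(p: Sequence[float], q: Sequence[float], clamp: float = 1e-12) -> float:
    """Multi-class cross-entropy H(p, q) = -sum_x p(x) log q(x).

    ``q`` is clamped at ``clamp`` to avoid log 0. Non-negative whenever
    ``p`` is one-hot, and 0 iff ``q`` puts mass 1 on the true class.
    """
    p_arr = np.asarray(p, dtype=np.float64)
    q_arr = np.asarray(q, dtype=np.float64)
    if p_arr.shape != q_arr.shape:
        raise ValueError(f"distribution lengths differ: {p_arr.shape} vs {q_arr.shape}")
    return float(-(p_arr * np.log(np.clip(q_arr, clamp, None))).sum()) + 0.0


def forward(x: PooledEmbedding | EmbeddingMatrix | np.ndarray, model: TrainedModel) -> ClassProbabilities:
    """Run the classifier on one input.

    A :class:`PooledEmbedding` (the default path) enters the GRU as a
    single timestep; an :class:`EmbeddingMatrix` engages the optional
    mode that runs the GRU over residues and pools after attention.
    """
    if isinstance(x, PooledEmbedding):
        X = x.x[None, :, :]  # (1, 1, D)
    elif isinstance(x, EmbeddingMatrix):
        X = x.values[None, :, :]  # (1, l, D)
    else:
        arr = np.asarray(x, dtype=np.float64)
        X = arr.reshape(1, -1, arr.shape[-1])
    if X.shape[2] != model.config.input_width:
        raise ValueError(
            f"input width {X.shape[2]} does not match model width {model.config.input_width}"
        )
    probs, _ = forward_pass(model.params, X, model.config)
    return ClassProbabilities(probs[0], model.label_map)


def predict(x, model: TrainedModel) -> int:
    """Predicted NS label: argmax of Y, ties toward the smaller label."""
    return forward(x, model).label


def predict_batch(X: np.ndarray, model: TrainedModel, batch_size: int = 4096) -> np.ndarray:
    """Predicted NS labels for an (N, D) matrix of pooled embeddings."""
    X = np.asarray(X, dtype=np.float64)
    labels = np.empty(X.shape[0], dtype=int)
    lm = np.asarray(model.label_map)
    for start in range(0, X.shape[0], batch_size):
        chunk = X[start : start + batch_size]
        probs, _ = forward_pass(model.params, chunk[:, None, :], model.config)
        labels[start : start + chunk.shape[0]] = lm[np.argmax(probs, axis=1)]
    return labels


def _as_arrays(
    dataset, label_map: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Accept list[(PooledEmbedding | vector, NS label)] or an (X, y) pair."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
    else:
        rows, y_list = [], []
        for emb, label in dataset:
            vec = emb.x if isinstance(emb, PooledEmbedding) else np.asarray(emb, float)
            rows.append(vec.reshape(-1))
            y_list.append(int(label))
        X = np.vstack(rows)
        y = np.asarray(y_list, dtype=int)
    index = {label: i for i, label in enumerate(label_map)}
    unknown = set(y.tolist()) - set(index)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} are outside the label map {tuple(label_map)}")
    y_idx = np.asarray([index[v] for v in y.tolist()], dtype=int)
    return X, y_idx


def train(
    dataset,
    config: DeepSubConfig | None = None,
    label_map: Sequence[int] = NS_LABELS,
) -> TrainedModel:
    """Train the classifier by mini-batch Adam on the cross-entropy loss.

    ``dataset`` is either a list of ``(PooledEmbedding, NS label)`` pairs
    or a ``(X, y)`` tuple with X of shape (N, input_width) and y holding
    NS labels. Fully reproducible given ``config.seed`` (initialisation,
    shuffling and dropout all derive from it). Records the mean loss of
    each epoch in the model history.
    """
    config = config or DeepSubConfig()
    X, y_idx = _as_arrays(dataset, label_map)
    if X.shape[1] != config.input_width:
        raise ValueError(
            f"embedding width {X.shape[1]} does not match config.input_width {config.input_width}"
        )
    if len(np.unique(y_idx)) < 2:
        raise ValueError("training requires at least 2 classes present")
    n = X.shape[0]
    C = config.n_classes
    onehot = np.eye(C)[y_idx]

    rng = np.random.Generator(np.random.PCG64(config.seed))
    params = init_params(config, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = X[idx][:, None, :]  # single timestep
            Yb = onehot[idx]
            probs, cache = forward_pass(params, Xb, config, dropout_rng=rng)
            batch_loss = float(
                -(Yb * np.log(np.clip(probs, 1e-12, None))).sum() / len(idx)
            )
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"loss={batch_loss}, max|logit input|={np.abs(cache['M_d']).max():.3g}"
                )
            epoch_loss += batch_loss * len(idx)
            grads = backward_pass(params, cache, Yb)
            step += 1
            for key in params:
                gk = grads[key]
                m[key] = beta1 * m[key] + (1 - beta1) * gk
                v[key] = beta2 * v[key] + (1 - beta2) * gk * gk
                mhat = m[key] / (1 - beta1**step)
                vhat = v[key] / (1 - beta2**step)
                params[key] = params[key] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(epoch_loss / n)

    return TrainedModel(params=params, config=config, label_map=tuple(label_map), history=history)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file checkpoint: weights + config + label map + schema version."""
    meta = {
        "schema_version": TrainedModel.SCHEMA_VERSION,
        "config": model.config.__dict__,
        "label_map": list(model.label_map),
        "history": model.history,
    }
    with open(path, "wb") as fh:  # keep the exact filename, whatever the suffix
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **model.params,
        )


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["schema_version"] != TrainedModel.SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return TrainedModel(
        params=params,
        config=DeepSubConfig(**meta["config"]),
        label_map=tuple(meta["label_map"]),
        history=list(meta["history"]),
    )
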