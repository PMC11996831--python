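"""Hybrid Transformer–CNN classifier with attention-weighted feature fusion.

The model takes a batch of fixed-length sequence embeddings and runs two
parallel branches:

* a Transformer-encoder branch in which, following the reference
  architecture's batch-as-tokens convention, the *samples of the batch*
  are the attention tokens (``token_mode="batch"``). Each prediction then
  depends on its evaluation batch, so evaluation uses one fixed,
  documented batch (the whole fold). A leakage-free per-sample mode
  (``token_mode="chunk"``) that splits one embedding into tokens is
  available behind the flag.
* a CNN branch that zero-pads each embedding to the next perfect square,
  reshapes it row-major to a single-channel square grid, and applies a
  valid convolution + ReLU + non-overlapping max pooling.

Branch outputs T and C are combined by a learned per-sample softmax gate
``a = softmax(W2 tanh(W1 [T;C] + b1) + b2)`` with ``a_t + a_c = 1``; the
gated, reweighted branches are concatenated and classified by a single
fully connected layer with a softmax over the two classes (decision
threshold 0.5). Ablation variants (plain concatenation, CNN-only,
Transformer-only) are selected through ``ModelConfig.variant``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .errors import ParameterError, ProtfuseError, ShapeError, TrainingDivergedError

VARIANTS = ("full", "no-fusion", "cnn-only", "transformer-only")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``d_model`` must equal the embedding dimension (num_feature) and be
    divisible by ``n_head`` so each head has width d_k = d_model / n_head.
    """

    d_model: int
    n_head: int = 4
    n_encoder_layers: int = 2
    conv_out_channels: int = 8
    kernel_h: int = 3
    kernel_w: int = 3
    pool_h: int = 2
    pool_w: int = 2
    fusion_hidden: int = 64
    variant: str = "full"
    token_mode: str = "batch"
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("d_model", "n_head", "n_encoder_layers", "conv_out_channels",
                     "kernel_h", "kernel_w", "pool_h", "pool_w", "fusion_hidden",
                     "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.d_model % self.n_head != 0:
            raise ParameterError(
                f"d_model ({self.d_model}) must be divisible by n_head ({self.n_head})"
            )
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.token_mode not in ("batch", "chunk"):
            raise ParameterError("token_mode must be 'batch' or 'chunk'")
        if not (0.0 <= self.dropout < 1.0):
            raise ParameterError("dropout must be in [0, 1)")
        side = grid_side(self.d_model)
        if self.kernel_h > side or self.kernel_w > side:
            raise ParameterError(
                f"conv kernel ({self.kernel_h}x{self.kernel_w}) exceeds grid side {side}"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_head

    @property
    def cnn_out_dim(self) -> int:
        side = grid_side(self.d_model)
        ho = (side - self.kernel_h + 1) // self.pool_h
        wo = (side - self.kernel_w + 1) // self.pool_w
        if ho < 1 or wo < 1:
            raise ParameterError("pooling window exceeds convolution output")
        return self.conv_out_channels * ho * wo

    @property
    def fused_dim(self) -> int:
        if self.variant == "cnn-only":
            return self.cnn_out_dim
        if self.variant == "transformer-only":
            return self.d_model
        return self.d_model + self.cnn_out_dim


def grid_side(num_feature: int) -> int:
    """Side of the smallest square grid holding ``num_feature`` entries."""
    return math.ceil(math.sqrt(num_feature))


def reshape_to_grid(x: np.ndarray) -> np.ndarray:
    """Zero-pad a feature vector (or batch of them) to the next perfect
    square and reshape row-major to a single-channel square grid."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    n, d = x.shape
    side = grid_side(d)
    padded = np.zeros((n, side * side))
    padded[:, :d] = x
    grids = padded.reshape(n, 1, side, side)
    return grids[0] if single else grids


def init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    """Seeded Xavier-uniform initialization of every trainable tensor."""
    rng = np.random.default_rng(config.seed)
    p: dict[str, np.ndarray] = {}
    d, dk, h = config.d_model, config.d_k, config.n_head
    if config.variant != "cnn-only":
        for layer in range(config.n_encoder_layers):
            pre = f"enc{layer}."
            for name in ("Wq", "Wk", "Wv"):
                p[pre + name] = _nn.xavier(rng, (h, d, dk), d, dk)
            p[pre + "Wo"] = _nn.xavier(rng, (d, d), d, d)
            p[pre + "ln1_g"] = np.ones(d)
            p[pre + "ln1_b"] = np.zeros(d)
            p[pre + "ln2_g"] = np.ones(d)
            p[pre + "ln2_b"] = np.zeros(d)
            p[pre + "W1"] = _nn.xavier(rng, (d, 4 * d), d, 4 * d)
            p[pre + "b1"] = np.zeros(4 * d)
            p[pre + "W2"] = _nn.xavier(rng, (4 * d, d), 4 * d, d)
            p[pre + "b2"] = np.zeros(d)
    if config.variant != "transformer-only":
        kh, kw, co = config.kernel_h, config.kernel_w, config.conv_out_channels
        p["conv_W"] = _nn.xavier(rng, (co, 1, kh, kw), kh * kw, co)
        p["conv_b"] = np.zeros(co)
    if config.variant == "full":
        dt, dc, fh = config.d_model, config.cnn_out_dim, config.fusion_hidden
        p["fus_W1"] = _nn.xavier(rng, (fh, dt + dc), dt + dc, fh)
        p["fus_b1"] = np.zeros(fh)
        p["fus_W2"] = _nn.xavier(rng, (2, fh), fh, 2)
        p["fus_b2"] = np.zeros(2)
        p["fus_Wt"] = _nn.xavier(rng, (dt, dt), dt, dt)
        p["fus_Wc"] = _nn.xavier(rng, (dc, dc), dc, dc)
    p["head_W"] = _nn.xavier(rng, (2, config.fused_dim), config.fused_dim, 2)
    p["head_b"] = np.zeros(2)
    return p


# ---------------------------------------------------------------------------
# public single-operation entry points (inference)
# ---------------------------------------------------------------------------

def attention_head(
    X: np.ndarray, Wq: np.ndarray, Wk: np.ndarray, Wv: np.ndarray,
    return_weights: bool = False,
):
    """One scaled-dot-product attention head over token matrix ``X``.

    Q = X Wq, K = X Wk, V = X Wv; A = softmax(Q K^T / sqrt(d_k)) row-wise;
    the head output is A V.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != Wq.shape[0]:
        raise ShapeError(f"token width {X.shape[1]} != projection input {Wq.shape[0]}")
    d_k = Wq.shape[1]
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    A = _nn.softmax(Q @ K.T / np.sqrt(d_k), axis=-1)
    O = A @ V
    return (O, A) if return_weights else O


def multi_head_attention(X: np.ndarray, params: dict, prefix: str = "") -> np.ndarray:
    """Concatenate all head outputs and project with W^O; width is preserved."""
    out, _ = _nn.mha_forward(np.asarray(X, dtype=np.float64), params, prefix)
    return out


def conv_forward(grid: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid convolution + ReLU over a (C_in, H, W) grid or (n, C_in, H, W) batch."""
    grid = np.asarray(grid, dtype=np.float64)
    single = grid.ndim == 3
    if single:
        grid = grid[None]
    out, _ = _nn.conv_relu_forward(grid, W, b)
    return out[0] if single else out


def max_pool(maps: np.ndarray, pool_h: int, pool_w: int) -> np.ndarray:
    """Non-overlapping max pooling with stride equal to the window."""
    maps = np.asarray(maps, dtype=np.float64)
    single = maps.ndim == 3
    if single:
        maps = maps[None]
    out, _ = _nn.maxpool_forward(maps, pool_h, pool_w)
    return out[0] if single else out


def fuse(T: np.ndarray, C: np.ndarray, params: dict):
    """Attention-weighted branch fusion; returns (F_fused, gate weights a)."""
    F, a, _ = _nn.fusion_forward(
        np.asarray(T, dtype=np.float64), np.asarray(C, dtype=np.float64), params
    )
    return F, a


# ---------------------------------------------------------------------------
# branches and full forward/backward
# ---------------------------------------------------------------------------

def _transformer_forward(X, config, params, rng=None):
    if X.shape[0] < 1:
        raise ShapeError("empty batch")
    caches = []
    if config.token_mode == "batch":
        tokens = X
    else:  # chunk: split each embedding into tokens of width d_model
        n, d = X.shape
        if d % config.d_model != 0:
            raise ShapeError(
                f"num_feature {d} not divisible by d_model {config.d_model} in chunk mode"
            )
        tokens = X.reshape(n * (d // config.d_model), config.d_model)
    h = tokens
    p_drop = config.dropout if rng is not None else 0.0
    for layer in range(config.n_encoder_layers):
        h, cache = _nn.encoder_block_forward(h, params, f"enc{layer}.", p_drop, rng)
        caches.append(cache)
    if config.token_mode == "chunk":
        n = X.shape[0]
        h = h.reshape(n, -1, config.d_model).mean(axis=1)
    return h, caches


def _transformer_backward(dT, config, params, caches, n_samples):
    if config.token_mode == "chunk":
        t = caches[-1][4].shape[0] // n_samples if caches else 1
        dT = np.repeat(dT / t, t, axis=0)
    grads = {}
    dh = dT
    for layer in reversed(range(config.n_encoder_layers)):
        dh, g = _nn.encoder_block_backward(dh, caches[layer], params)
        grads.update(g)
    return grads


def transformer_branch(X: np.ndarray, config: ModelConfig, params: dict) -> np.ndarray:
    """Encoder-branch features T, one row per sample (inference mode)."""
    if config.n_encoder_layers < 1:
        raise ParameterError("n_encoder_layers must be >= 1")
    T, _ = _transformer_forward(np.asarray(X, dtype=np.float64), config, params)
    return T


def _cnn_forward(X, config, params):
    grids = reshape_to_grid(X)
    fmaps, conv_cache = _nn.conv_relu_forward(grids, params["conv_W"], params["conv_b"])
    pooled, pool_cache = _nn.maxpool_forward(fmaps, config.pool_h, config.pool_w)
    C = pooled.reshape(X.shape[0], -1)
    return C, (conv_cache, pool_cache, pooled.shape, X.shape[1])


def _cnn_backward(dC, cache):
    conv_cache, pool_cache, pooled_shape, d_in = cache
    dpooled = dC.reshape(pooled_shape)
    dfmaps = _nn.maxpool_backward(dpooled, pool_cache)
    _, grads = _nn.conv_relu_backward(dfmaps, conv_cache)
    return {"conv_W": grads["W"], "conv_b": grads["b"]}


def cnn_branch(X: np.ndarray, config: ModelConfig, params: dict) -> np.ndarray:
    """CNN-branch features C: grid reshape, conv+ReLU, max-pool, flatten."""
    C, _ = _cnn_forward(np.asarray(X, dtype=np.float64), config, params)
    return C


def _forward_full(X, config, params, rng=None):
    """Forward pass returning (probs, logits, caches) for all variants."""
    caches = {}
    T = C = None
    if config.variant != "cnn-only":
        T, caches["enc"] = _transformer_forward(X, config, params, rng)
    if config.variant != "transformer-only":
        C, caches["cnn"] = _cnn_forward(X, config, params)
    if config.variant == "full":
        F, a, caches["fus"] = _nn.fusion_forward(T, C, params)
        caches["a"] = a
    elif config.variant == "no-fusion":
        F = np.concatenate([T, C], axis=1)
    elif config.variant == "cnn-only":
        F = C
    else:
        F = T
    logits = F @ params["head_W"].T + params["head_b"]
    caches["F"] = F
    probs = _nn.softmax(logits, axis=-1)
    if not np.all(np.isfinite(logits)):
        raise ProtfuseError(
            f"non-finite activations in forward pass (variant={config.variant}, "
            f"|logits|max={np.nanmax(np.abs(logits))})"
        )
    return probs, logits, caches


def _backward_full(d_logits, X, config, params, caches):
    grads = {"head_W": d_logits.T @ caches["F"], "head_b": d_logits.sum(axis=0)}
    dF = d_logits @ params["head_W"]
    dT = dC = None
    if config.variant == "full":
        dT, dC, g = _nn.fusion_backward(dF, caches["fus"])
        grads.update(g)
    elif config.variant == "no-fusion":
        dT, dC = dF[:, : config.d_model], dF[:, config.d_model :]
    elif config.variant == "cnn-only":
        dC = dF
    else:
        dT = dF
    if dC is not None:
        grads.update(_cnn_backward(dC, caches["cnn"]))
    if dT is not None:
        grads.update(_transformer_backward(dT, config, params, caches["enc"], X.shape[0]))
    return grads


def forward(X: np.ndarray, config: ModelConfig, params: dict) -> np.ndarray:
    """Positive-class probability per sample (inference mode, no dropout).

    In the default batch-as-tokens mode the whole input batch is the
    attention context, so callers must pass the same fixed batch they
    intend to evaluate.
    """
    X = np.asarray(X, dtype=np.float64)
    probs, _, _ = _forward_full(X, config, params)
    return probs[:, 1]


def predict_labels(X: np.ndarray, config: ModelConfig, params: dict) -> np.ndarray:
    return (forward(X, config, params) >= 0.5).astype(int)


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[dict, list[float]]:
    """Train by mini-batch Adam on softmax cross-entropy.

    Early stopping monitors validation loss when ``validation`` is given
    (patience ``config.patience``), otherwise the training loss. Returns
    the best parameters and the per-epoch training-loss trace. Fully
    reproducible from ``config.seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ShapeError(f"X rows {X.shape[0]} != labels {y.shape[0]}")
    if X.shape[1] != config.d_model and config.token_mode == "batch":
        raise ShapeError(
            f"embedding width {X.shape[1]} != d_model {config.d_model}"
        )
    params = init_params(config)
    opt = _nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    trace: list[float] = []
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stale = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            drop_rng = rng if config.dropout > 0 else None
            try:
                probs, logits, caches = _forward_full(X[idx], config, params, drop_rng)
            except ProtfuseError as exc:
                raise TrainingDivergedError(
                    f"training diverged at epoch {_epoch}: {exc}", checkpoint=best_params
                ) from exc
            loss, _, d_logits = _nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"training loss diverged at epoch {_epoch}", checkpoint=best_params
                )
            grads = _backward_full(d_logits, X[idx], config, params, caches)
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
        if validation is not None:
            Xv, yv = validation
            _, vlogits, _ = _forward_full(np.asarray(Xv, dtype=np.float64), config, params)
            monitor, _, _ = _nn.cross_entropy(vlogits, np.asarray(yv, dtype=int))
        else:
            monitor = trace[-1]
        if monitor < best_loss - 1e-6:
            best_loss = monitor
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return best_params, trace


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(params: dict, config: ModelConfig, path) -> None:
    """Single-file checkpoint: all weight tensors + the full ModelConfig."""
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    ), **params)


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        config = ModelConfig(**cfg_raw)
        params = {k: data[k] for k in data.files if k != "__config__"}
    return params, config
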