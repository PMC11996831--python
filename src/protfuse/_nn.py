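"""Low-level neural-network primitives (NumPy forward + backward passes).

Every forward function returns ``(output, cache)`` and has a matching
backward function consuming ``(d_output, cache)`` and returning the input
gradient plus a dict of parameter gradients. Shapes follow the row-major
convention: a token/sample matrix is ``(n, d)``.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(d_out: np.ndarray, out: np.ndarray, axis: int = -1) -> np.ndarray:
    """Jacobian-vector product of softmax given its output."""
    return out * (d_out - np.sum(d_out * out, axis=axis, keepdims=True))


def xavier(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# multi-head scaled-dot-product self-attention
# ---------------------------------------------------------------------------

def mha_forward(X: np.ndarray, params: dict, prefix: str = ""):
    """Multi-head self-attention over the token axis.

    ``params[prefix+"Wq"]`` etc. have shape ``(n_head, d_model, d_k)``;
    ``params[prefix+"Wo"]`` is ``(d_model, d_model)``.
    """
    Wq, Wk, Wv, Wo = (params[prefix + k] for k in ("Wq", "Wk", "Wv", "Wo"))
    n, d_model = X.shape
    n_head, d_in, d_k = Wq.shape
    if d_in != d_model:
        raise ShapeError(f"token width {d_model} != projection input {d_in}")
    Q = np.einsum("nd,hdk->hnk", X, Wq)
    K = np.einsum("nd,hdk->hnk", X, Wk)
    V = np.einsum("nd,hdk->hnk", X, Wv)
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(d_k)
    A = softmax(S, axis=-1)  # (h, n, n); each row sums to 1
    O = A @ V  # (h, n, d_k)
    concat = O.transpose(1, 0, 2).reshape(n, n_head * d_k)
    out = concat @ Wo
    cache = (X, Q, K, V, A, concat, Wq, Wk, Wv, Wo, prefix)
    return out, cache


def mha_backward(d_out: np.ndarray, cache):
    X, Q, K, V, A, concat, Wq, Wk, Wv, Wo, prefix = cache
    n, d_model = X.shape
    n_head, _, d_k = Wq.shape
    grads = {}
    grads[prefix + "Wo"] = concat.T @ d_out
    d_concat = d_out @ Wo.T
    dO = d_concat.reshape(n, n_head, d_k).transpose(1, 0, 2)
    dA = dO @ V.transpose(0, 2, 1)
    dV = A.transpose(0, 2, 1) @ dO
    dS = softmax_backward(dA, A) / np.sqrt(d_k)
    dQ = dS @ K
    dK = dS.transpose(0, 2, 1) @ Q
    grads[prefix + "Wq"] = np.einsum("nd,hnk->hdk", X, dQ)
    grads[prefix + "Wk"] = np.einsum("nd,hnk->hdk", X, dK)
    grads[prefix + "Wv"] = np.einsum("nd,hnk->hdk", X, dV)
    dX = (
        np.einsum("hnk,hdk->nd", dQ, Wq)
        + np.einsum("hnk,hdk->nd", dK, Wk)
        + np.einsum("hnk,hdk->nd", dV, Wv)
    )
    return dX, grads


# ---------------------------------------------------------------------------
# layer normalization, feed-forward, dropout
# ---------------------------------------------------------------------------

def layernorm_forward(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(d_out: np.ndarray, cache):
    xhat, inv, g = cache
    dg = (d_out * xhat).sum(axis=0)
    db = d_out.sum(axis=0)
    dxhat = d_out * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


def dropout_forward(x: np.ndarray, p: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when ``p == 0`` or ``rng`` is None (eval)."""
    if p <= 0.0 or rng is None:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_backward(d_out: np.ndarray, mask):
    return d_out if mask is None else d_out * mask


# ---------------------------------------------------------------------------
# pre-norm transformer encoder block
# ---------------------------------------------------------------------------

def encoder_block_forward(x, params, prefix, dropout_p=0.0, rng=None):
    """x + Drop(MHA(LN1(x))); then h + Drop(FFN(LN2(h))) with ReLU FFN."""
    a, ln1_cache = layernorm_forward(x, params[prefix + "ln1_g"], params[prefix + "ln1_b"])
    m, mha_cache = mha_forward(a, params, prefix)
    m_d, mask1 = dropout_forward(m, dropout_p, rng)
    h = x + m_d
    f, ln2_cache = layernorm_forward(h, params[prefix + "ln2_g"], params[prefix + "ln2_b"])
    pre = f @ params[prefix + "W1"] + params[prefix + "b1"]
    act = np.maximum(pre, 0.0)
    o = act @ params[prefix + "W2"] + params[prefix + "b2"]
    o_d, mask2 = dropout_forward(o, dropout_p, rng)
    out = h + o_d
    cache = (ln1_cache, mha_cache, mask1, ln2_cache, f, pre, act, mask2, prefix)
    return out, cache


def encoder_block_backward(d_out, cache, params):
    ln1_cache, mha_cache, mask1, ln2_cache, f, pre, act, mask2, prefix = cache
    grads = {}
    do = dropout_backward(d_out, mask2)
    grads[prefix + "W2"] = act.T @ do
    grads[prefix + "b2"] = do.sum(axis=0)
    dact = do @ params[prefix + "W2"].T
    dpre = dact * (pre > 0)
    grads[prefix + "W1"] = f.T @ dpre
    grads[prefix + "b1"] = dpre.sum(axis=0)
    df = dpre @ params[prefix + "W1"].T
    dh_ln, dg2, db2 = layernorm_backward(df, ln2_cache)
    grads[prefix + "ln2_g"] = dg2
    grads[prefix + "ln2_b"] = db2
    dh = d_out + dh_ln  # residual
    dm = dropout_backward(dh, mask1)
    da, mha_grads = mha_backward(dm, mha_cache)
    grads.update(mha_grads)
    dx_ln, dg1, db1 = layernorm_backward(da, ln1_cache)
    grads[prefix + "ln1_g"] = dg1
    grads[prefix + "ln1_b"] = db1
    dx = dh + dx_ln  # residual
    return dx, grads


# ---------------------------------------------------------------------------
# convolution (valid, stride 1) + ReLU, and non-overlapping max pooling
# ---------------------------------------------------------------------------

def conv_relu_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (n, C_in, H, W); W: (C_out, C_in, K_h, K_w); valid extent, ReLU."""
    n, c_in, H, Wd = x.shape
    c_out, c_in_w, kh, kw = W.shape
    if c_in != c_in_w:
        raise ShapeError(f"input channels {c_in} != kernel channels {c_in_w}")
    if kh > H or kw > Wd:
        raise ShapeError(f"kernel ({kh}x{kw}) larger than grid ({H}x{Wd})")
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    pre = np.einsum("ncijpq,ocpq->noij", windows, W) + b[None, :, None, None]
    out = np.maximum(pre, 0.0)
    return out, (x, windows, W, pre)


def conv_relu_backward(d_out: np.ndarray, cache):
    x, windows, W, pre = cache
    c_out, c_in, kh, kw = W.shape
    dpre = d_out * (pre > 0)
    dW = np.einsum("ncijpq,noij->ocpq", windows, dpre)
    db = dpre.sum(axis=(0, 2, 3))
    dx = np.zeros_like(x)
    ho, wo = dpre.shape[2], dpre.shape[3]
    for p in range(kh):
        for q in range(kw):
            # dpre (n,o,i,j) x W[:, :, p, q] (o,c) -> (n,c,i,j)
            dx[:, :, p : p + ho, q : q + wo] += np.einsum(
                "noij,oc->ncij", dpre, W[:, :, p, q]
            )
    return dx, {"W": dW, "b": db}


def maxpool_forward(x: np.ndarray, ph: int, pw: int):
    """Non-overlapping max pooling, stride = window; trailing remainder cropped."""
    n, c, H, Wd = x.shape
    if ph > H or pw > Wd:
        raise ShapeError(f"pool window ({ph}x{pw}) exceeds map ({H}x{Wd})")
    ho, wo = H // ph, Wd // pw
    xr = x[:, :, : ho * ph, : wo * pw]
    wins = xr.reshape(n, c, ho, ph, wo, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, ph * pw
    )
    idx = wins.argmax(axis=-1)  # first max wins ties: deterministic
    out = np.take_along_axis(wins, idx[..., None], axis=-1)[..., 0]
    return out, (x.shape, ho, wo, ph, pw, idx)


def maxpool_backward(d_out: np.ndarray, cache):
    shape, ho, wo, ph, pw, idx = cache
    n, c, H, Wd = shape
    dwins = np.zeros((n, c, ho, wo, ph * pw))
    np.put_along_axis(dwins, idx[..., None], d_out[..., None], axis=-1)
    dx = np.zeros(shape)
    dx[:, :, : ho * ph, : wo * pw] = (
        dwins.reshape(n, c, ho, wo, ph, pw).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * ph, wo * pw
        )
    )
    return dx


# ---------------------------------------------------------------------------
# attention-weighted feature fusion
# ---------------------------------------------------------------------------

def fusion_forward(T: np.ndarray, C: np.ndarray, params: dict):
    """Per-sample softmax gate over the two branches.

    a = softmax(W2 tanh(W1 [T;C] + b1) + b2); the first gate component
    weights the transformer branch, the second the CNN branch:
    T' = a_t (T Wt^T), C' = a_c (C Wc^T); F = [T'; C'].
    """
    if T.shape[0] != C.shape[0]:
        raise ShapeError(f"branch row counts differ: {T.shape[0]} vs {C.shape[0]}")
    Z = np.concatenate([T, C], axis=1)
    H1 = np.tanh(Z @ params["fus_W1"].T + params["fus_b1"])
    logits = H1 @ params["fus_W2"].T + params["fus_b2"]
    a = softmax(logits, axis=-1)  # (n, 2); rows sum to 1
    Tw = T @ params["fus_Wt"].T
    Cw = C @ params["fus_Wc"].T
    Tp = a[:, 0:1] * Tw
    Cp = a[:, 1:2] * Cw
    F = np.concatenate([Tp, Cp], axis=1)
    cache = (T, C, Z, H1, a, Tw, Cw, params)
    return F, a, cache


def fusion_backward(dF: np.ndarray, cache):
    T, C, Z, H1, a, Tw, Cw, params = cache
    dt, dc = Tw.shape[1], Cw.shape[1]
    dTp, dCp = dF[:, :dt], dF[:, dt:]
    grads = {}
    da = np.concatenate(
        [(dTp * Tw).sum(axis=1, keepdims=True), (dCp * Cw).sum(axis=1, keepdims=True)],
        axis=1,
    )
    dTw = dTp * a[:, 0:1]
    dCw = dCp * a[:, 1:2]
    grads["fus_Wt"] = dTw.T @ T
    grads["fus_Wc"] = dCw.T @ C
    dT = dTw @ params["fus_Wt"]
    dC = dCw @ params["fus_Wc"]
    dlogits = softmax_backward(da, a)
    grads["fus_W2"] = dlogits.T @ H1
    grads["fus_b2"] = dlogits.sum(axis=0)
    dH1 = dlogits @ params["fus_W2"]
    dpre = dH1 * (1.0 - H1**2)
    grads["fus_W1"] = dpre.T @ Z
    grads["fus_b1"] = dpre.sum(axis=0)
    dZ = dpre @ params["fus_W1"]
    dT = dT + dZ[:, :dt]
    dC = dC + dZ[:, dt:]
    return dT, dC, grads


# ---------------------------------------------------------------------------
# softmax cross-entropy head
# ---------------------------------------------------------------------------

def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy; returns (loss, probs, d_logits)."""
    probs = softmax(logits, axis=-1)
    n = len(y)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), y] + eps))
    d_logits = probs.copy()
    d_logits[np.arange(n), y] -= 1.0
    d_logits /= n
    return loss, probs, d_logits


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
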