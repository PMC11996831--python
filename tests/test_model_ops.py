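"""Model building blocks against independent loop-written oracles.

Each oracle re-implements one operation term by term with explicit Python
loops, sharing no code with the vectorized implementation under test.
"""

import math

import numpy as np
import pytest

from protfuse import _nn
from protfuse.errors import ParameterError, ShapeError
from protfuse.model import (
    ModelConfig,
    attention_head,
    cnn_branch,
    conv_forward,
    forward,
    fuse,
    init_params,
    max_pool,
    multi_head_attention,
    reshape_to_grid,
    transformer_branch,
)

# ---------------------------------------------------------------------------
# loop-written oracles
# ---------------------------------------------------------------------------


def oracle_attention_head(X, Wq, Wk, Wv):
    n, _ = X.shape
    d_k = Wq.shape[1]
    Q = [[sum(X[t][d] * Wq[d][k] for d in range(X.shape[1])) for k in range(d_k)]
         for t in range(n)]
    K = [[sum(X[t][d] * Wk[d][k] for d in range(X.shape[1])) for k in range(d_k)]
         for t in range(n)]
    V = [[sum(X[t][d] * Wv[d][k] for d in range(X.shape[1])) for k in range(d_k)]
         for t in range(n)]
    A = []
    for i in range(n):
        scores = [sum(Q[i][k] * K[j][k] for k in range(d_k)) / math.sqrt(d_k)
                  for j in range(n)]
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        z = sum(exps)
        A.append([e / z for e in exps])
    O = [[sum(A[i][j] * V[j][k] for j in range(n)) for k in range(d_k)] for i in range(n)]
    return np.array(O), np.array(A)


def oracle_multi_head(X, Wq, Wk, Wv, Wo):
    n_head = Wq.shape[0]
    heads = [oracle_attention_head(X, Wq[h], Wk[h], Wv[h])[0] for h in range(n_head)]
    n = X.shape[0]
    concat = [[heads[h][t][k] for h in range(n_head) for k in range(heads[h].shape[1])]
              for t in range(n)]
    d_model = Wo.shape[0]
    out = [[sum(concat[t][d] * Wo[d][e] for d in range(d_model)) for e in range(Wo.shape[1])]
           for t in range(n)]
    return np.array(out)


def oracle_conv_relu(x, W, b):
    c_in, H, Wd = x.shape
    c_out, _, kh, kw = W.shape
    out = np.zeros((c_out, H - kh + 1, Wd - kw + 1))
    for o in range(c_out):
        for i in range(H - kh + 1):
            for j in range(Wd - kw + 1):
                acc = b[o]
                for c in range(c_in):
                    for p in range(kh):
                        for q in range(kw):
                            acc += W[o][c][p][q] * x[c][i + p][j + q]
                out[o][i][j] = max(0.0, acc)
    return out


def oracle_max_pool(x, ph, pw):
    c, H, Wd = x.shape
    ho, wo = H // ph, Wd // pw
    out = np.zeros((c, ho, wo))
    for k in range(c):
        for i in range(ho):
            for j in range(wo):
                out[k][i][j] = max(
                    x[k][i * ph + p][j * pw + q] for p in range(ph) for q in range(pw)
                )
    return out


def oracle_fuse(T, C, params):
    n, dt = T.shape
    dc = C.shape[1]
    W1, b1 = params["fus_W1"], params["fus_b1"]
    W2, b2 = params["fus_W2"], params["fus_b2"]
    Wt, Wc = params["fus_Wt"], params["fus_Wc"]
    F = np.zeros((n, dt + dc))
    gates = np.zeros((n, 2))
    for s in range(n):
        z = list(T[s]) + list(C[s])
        h = [math.tanh(sum(W1[r][d] * z[d] for d in range(len(z))) + b1[r])
             for r in range(W1.shape[0])]
        logits = [sum(W2[g][r] * h[r] for r in range(len(h))) + b2[g] for g in range(2)]
        m = max(logits)
        exps = [math.exp(v - m) for v in logits]
        a = [e / sum(exps) for e in exps]
        Tp = [a[0] * sum(Wt[r][d] * T[s][d] for d in range(dt)) for r in range(dt)]
        Cp = [a[1] * sum(Wc[r][d] * C[s][d] for d in range(dc)) for r in range(dc)]
        F[s] = Tp + Cp
        gates[s] = a
    return F, gates


# ---------------------------------------------------------------------------
# oracle-equivalence on random instances
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("trial", range(20))
def test_attention_head_matches_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n, d, dk = rng.integers(2, 6), 4, 3
    X = rng.normal(size=(n, d))
    Wq, Wk, Wv = (rng.normal(size=(d, dk)) for _ in range(3))
    O, A = attention_head(X, Wq, Wk, Wv, return_weights=True)
    O2, A2 = oracle_attention_head(X, Wq, Wk, Wv)
    np.testing.assert_allclose(O, O2, atol=1e-10)
    np.testing.assert_allclose(A, A2, atol=1e-10)
    np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


@pytest.mark.parametrize("trial", range(20))
def test_multi_head_attention_matches_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    n, d, h = int(rng.integers(2, 5)), 6, 2
    dk = d // h
    X = rng.normal(size=(n, d))
    params = {
        "Wq": rng.normal(size=(h, d, dk)),
        "Wk": rng.normal(size=(h, d, dk)),
        "Wv": rng.normal(size=(h, d, dk)),
        "Wo": rng.normal(size=(d, d)),
    }
    out = multi_head_attention(X, params)
    expected = oracle_multi_head(X, params["Wq"], params["Wk"], params["Wv"], params["Wo"])
    np.testing.assert_allclose(out, expected, atol=1e-10)
    assert out.shape == X.shape  # width preserved


@pytest.mark.parametrize("trial", range(20))
def test_conv_forward_matches_oracle(trial):
    rng = np.random.default_rng(300 + trial)
    x = rng.normal(size=(1, 5, 5))
    W = rng.normal(size=(2, 1, 3, 3))
    b = rng.normal(size=2)
    np.testing.assert_allclose(conv_forward(x, W, b), oracle_conv_relu(x, W, b), atol=1e-10)


@pytest.mark.parametrize("trial", range(20))
def test_max_pool_matches_oracle(trial):
    rng = np.random.default_rng(400 + trial)
    x = rng.normal(size=(2, 6, 6))
    np.testing.assert_allclose(max_pool(x, 2, 2), oracle_max_pool(x, 2, 2), atol=1e-12)


@pytest.mark.parametrize("trial", range(20))
def test_fuse_matches_oracle(trial):
    rng = np.random.default_rng(500 + trial)
    n, dt, dc, fh = 4, 5, 3, 6
    T, C = rng.normal(size=(n, dt)), rng.normal(size=(n, dc))
    params = {
        "fus_W1": rng.normal(size=(fh, dt + dc)),
        "fus_b1": rng.normal(size=fh),
        "fus_W2": rng.normal(size=(2, fh)),
        "fus_b2": rng.normal(size=2),
        "fus_Wt": rng.normal(size=(dt, dt)),
        "fus_Wc": rng.normal(size=(dc, dc)),
    }
    F, a = fuse(T, C, params)
    F2, a2 = oracle_fuse(T, C, params)
    np.testing.assert_allclose(F, F2, atol=1e-10)
    np.testing.assert_allclose(a, a2, atol=1e-10)
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# analytic special cases
# ---------------------------------------------------------------------------


def test_single_token_attention_is_identity_on_v():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(1, 4))
    Wq, Wk, Wv = (rng.normal(size=(4, 2)) for _ in range(3))
    O, A = attention_head(X, Wq, Wk, Wv, return_weights=True)
    np.testing.assert_allclose(A, [[1.0]])
    np.testing.assert_allclose(O, X @ Wv)


def test_single_head_with_identity_output_projection():
    rng = np.random.default_rng(1)
    d = 4
    X = rng.normal(size=(3, d))
    params = {
        "Wq": rng.normal(size=(1, d, d)),
        "Wk": rng.normal(size=(1, d, d)),
        "Wv": rng.normal(size=(1, d, d)),
        "Wo": np.eye(d),
    }
    out = multi_head_attention(X, params)
    head = attention_head(X, params["Wq"][0], params["Wk"][0], params["Wv"][0])
    np.testing.assert_allclose(out, head, atol=1e-12)


def test_attention_width_mismatch_raises():
    with pytest.raises(ShapeError):
        attention_head(np.zeros((2, 3)), np.zeros((4, 2)), np.zeros((4, 2)), np.zeros((4, 2)))


class TestReshapeToGrid:
    def test_perfect_square_no_padding(self):
        x = np.arange(16.0)
        grid = reshape_to_grid(x)
        assert grid.shape == (1, 4, 4)
        np.testing.assert_array_equal(grid[0], x.reshape(4, 4))

    def test_1280_pads_to_36x36(self):
        grid = reshape_to_grid(np.ones(1280))
        assert grid.shape == (1, 36, 36)
        assert grid.sum() == 1280  # 16 zero pads

    def test_flatten_restores_vector_then_zeros(self):
        x = np.arange(10.0) + 1
        flat = reshape_to_grid(x).ravel()
        np.testing.assert_array_equal(flat[:10], x)
        np.testing.assert_array_equal(flat[10:], 0.0)


class TestConvPool:
    def test_identity_kernel_is_relu(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 4, 4))
        out = conv_forward(x, np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(out, np.maximum(x, 0))

    def test_relu_floor_on_negative_input(self):
        x = -np.ones((1, 4, 4))
        out = conv_forward(x, np.abs(np.random.default_rng(3).normal(size=(2, 1, 2, 2))),
                           np.zeros(2))
        assert np.all(out == 0)

    def test_kernel_larger_than_grid_raises(self):
        with pytest.raises(ShapeError):
            conv_forward(np.zeros((1, 2, 2)), np.zeros((1, 1, 3, 3)), np.zeros(1))

    def test_pool_constant_map(self):
        np.testing.assert_array_equal(max_pool(np.full((1, 4, 4), 2.5), 2, 2),
                                      np.full((1, 2, 2), 2.5))

    def test_pool_single_window(self):
        out = max_pool(np.array([[[1.0, 2.0], [3.0, 4.0]]]), 2, 2)
        np.testing.assert_array_equal(out, [[[4.0]]])

    def test_pool_window_exceeds_map_raises(self):
        with pytest.raises(ShapeError):
            max_pool(np.zeros((1, 2, 2)), 3, 3)


class TestFusionSpecialCases:
    def test_zero_scoring_weights_give_uniform_gate(self):
        rng = np.random.default_rng(4)
        T, C = rng.normal(size=(3, 4)), rng.normal(size=(3, 2))
        params = {
            "fus_W1": np.zeros((5, 6)), "fus_b1": np.zeros(5),
            "fus_W2": np.zeros((2, 5)), "fus_b2": np.zeros(2),
            "fus_Wt": rng.normal(size=(4, 4)), "fus_Wc": rng.normal(size=(2, 2)),
        }
        F, a = fuse(T, C, params)
        np.testing.assert_allclose(a, 0.5)
        assert F.shape == (3, 6)

    def test_row_count_mismatch_raises(self):
        with pytest.raises(ShapeError):
            _nn.fusion_forward(np.zeros((2, 3)), np.zeros((3, 3)), {})


class TestBranches:
    def cfg(self, **kw):
        defaults = dict(d_model=16, n_head=2, n_encoder_layers=2, conv_out_channels=3,
                        kernel_h=2, kernel_w=2, pool_h=1, pool_w=1, dropout=0.0, seed=0)
        defaults.update(kw)
        return ModelConfig(**defaults)

    def test_transformer_branch_permutation_equivariant(self):
        config = self.cfg()
        params = init_params(config)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 16))
        perm = rng.permutation(7)
        T = transformer_branch(X, config, params)
        T_perm = transformer_branch(X[perm], config, params)
        np.testing.assert_allclose(T_perm, T[perm], atol=1e-10)

    def test_batch_of_one_runs(self):
        config = self.cfg()
        params = init_params(config)
        T = transformer_branch(np.ones((1, 16)), config, params)
        assert T.shape == (1, 16)

    def test_zero_encoder_layers_rejected(self):
        with pytest.raises(ParameterError):
            self.cfg(n_encoder_layers=0)

    def test_cnn_branch_composes_reshape_conv_pool(self):
        config = self.cfg()
        params = init_params(config)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 16))
        C = cnn_branch(X, config, params)
        for s in range(4):
            grid = reshape_to_grid(X[s])
            fmaps = oracle_conv_relu(grid, params["conv_W"], params["conv_b"])
            pooled = oracle_max_pool(fmaps, config.pool_h, config.pool_w)
            np.testing.assert_allclose(C[s], pooled.ravel(), atol=1e-10)
        assert len({row.shape for row in C}) == 1  # same width for every sample

    def test_forward_probabilities_valid_and_deterministic(self):
        config = self.cfg()
        params = init_params(config)
        X = np.random.default_rng(7).normal(size=(6, 16))
        p1 = forward(X, config, params)
        p2 = forward(X, config, params)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(p1, p2)


class TestModelConfig:
    def test_dk_times_nhead_is_dmodel(self):
        config = ModelConfig(d_model=64, n_head=4)
        assert config.d_k * config.n_head == config.d_model

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(d_model=10, n_head=4)

    def test_invalid_variant_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(d_model=16, variant="both")
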