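import numpy as np
import pytest

from mtloc.autodiff import Tensor
from mtloc.config import ModelConfig
from mtloc.contact_graph import build_contact_map
from mtloc.gt_encoder import GTEncoder, GTLayer, InputProjection

from .conftest import random_backbone


def small_config(**kw):
    base = dict(d_h=5, d_e=7, d_p=8, h_d=2, n_gt_layers=2, d_fe=8, d_f=8,
                h_ki=2, m_bp=3, m_cc=2, m_mf=2, c_sl=2)
    base.update(kw)
    return ModelConfig(**base)


def random_graph(rng, n, cfg, threshold=7.0):
    coords = random_backbone(rng, n)
    edge_index = build_contact_map(coords, threshold)
    H = rng.standard_normal((n, cfg.d_h))
    E = rng.standard_normal((edge_index.shape[0], cfg.d_e))
    return H, E, edge_index


# -- loop-based oracle ---------------------------------------------------------

def _bn_eval(bn, X):
    norm = (X - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
    return norm * bn.gamma.data + bn.beta.data


def _silu(x):
    return x / (1.0 + np.exp(-x))


def oracle_gt_layer(layer, H, E, edge_index):
    """Plain-numpy per-edge/per-node re-implementation of one layer (eval
    mode).  Returns (H_next, E_next, attention weights)."""
    Hn, En = _bn_eval(layer.norm_h, H), _bn_eval(layer.norm_e, E)
    Q, K = Hn @ layer.W_Q.W.data, Hn @ layer.W_K.W.data
    V, Ep = Hn @ layer.W_V.W.data, En @ layer.W_E.W.data
    n = H.shape[0]
    scores = np.empty_like(Ep)
    for k, (i, j) in enumerate(edge_index):
        scores[k] = Q[i] * K[j] / np.sqrt(layer.d_k) * Ep[k]
    w = np.empty_like(scores)
    for i in range(n):
        mask = edge_index[:, 0] == i
        if mask.any():
            s = scores[mask]
            e = np.exp(s - s.max(axis=0))
            w[mask] = e / e.sum(axis=0)
    agg = np.zeros_like(H, dtype=float)
    for k, (i, j) in enumerate(edge_index):
        agg[i] += w[k] * V[j]
    H_bar = H + agg @ layer.W_h0.W.data
    E_bar = E + w @ layer.W_e0.W.data
    H_next = H_bar + _silu(
        _bn_eval(layer.norm_h_ffn, H_bar) @ layer.W_h1.W.data
    ) @ layer.W_h2.W.data
    E_next = E_bar + _silu(
        _bn_eval(layer.norm_e_ffn, E_bar) @ layer.W_e1.W.data
    ) @ layer.W_e2.W.data
    return H_next, E_next, w


def test_layer_matches_loop_oracle_on_random_graphs():
    cfg = small_config()
    rng = np.random.default_rng(0)
    layer = GTLayer(cfg, np.random.default_rng(1))
    layer.eval()
    for _ in range(10):
        n = int(rng.integers(4, 13))
        coords = random_backbone(rng, n)
        edge_index = build_contact_map(coords, 7.0)
        H = rng.standard_normal((n, cfg.d_p))
        E = rng.standard_normal((edge_index.shape[0], cfg.d_p))
        state = layer(_state(H, E), edge_index)
        H_ref, E_ref, _ = oracle_gt_layer(layer, H, E, edge_index)
        np.testing.assert_allclose(state.H.data, H_ref, atol=1e-10)
        np.testing.assert_allclose(state.E.data, E_ref, atol=1e-10)


def _state(H, E):
    from mtloc.gt_encoder import GTState
    wrap = lambda x: x if isinstance(x, Tensor) else Tensor(x)
    return GTState(wrap(H), wrap(E))


def test_attention_weights_sum_to_one_per_neighbourhood():
    cfg = small_config()
    rng = np.random.default_rng(4)
    layer = GTLayer(cfg, np.random.default_rng(5))
    n = 10
    coords = random_backbone(rng, n)
    edge_index = build_contact_map(coords, 8.0)
    H = rng.standard_normal((n, cfg.d_p))
    E = rng.standard_normal((edge_index.shape[0], cfg.d_p))
    _, _, w = oracle_gt_layer(layer, H, E, edge_index)
    for i in range(n):
        mask = edge_index[:, 0] == i
        if mask.any():
            np.testing.assert_allclose(w[mask].sum(axis=0), 1.0, atol=1e-12)


def test_encoder_permutation_equivariance():
    """Relabelling the residues permutes the encoder's node output rows."""
    cfg = small_config()
    rng = np.random.default_rng(8)
    enc = GTEncoder(cfg, np.random.default_rng(9))
    enc.eval()
    H, E, edge_index = random_graph(rng, 12, cfg)

    perm = rng.permutation(12)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(12)
    H_p = H[perm]
    edge_p = inv[edge_index]  # same edges under new labels, same row order
    out = enc(Tensor(H), Tensor(E), edge_index)
    out_p = enc(Tensor(H_p), Tensor(E), edge_p)
    np.testing.assert_allclose(out_p.H.data, out.H.data[perm], atol=1e-9)
    np.testing.assert_allclose(out_p.E.data, out.E.data, atol=1e-9)


def test_encoder_output_shapes_and_determinism():
    cfg = small_config()
    rng = np.random.default_rng(2)
    enc = GTEncoder(cfg, np.random.default_rng(3))
    enc.eval()
    H, E, edge_index = random_graph(rng, 9, cfg)
    s1 = enc(Tensor(H), Tensor(E), edge_index)
    s2 = enc(Tensor(H), Tensor(E), edge_index)
    assert s1.H.shape == (9, cfg.d_p)
    assert s1.E.shape == (edge_index.shape[0], cfg.d_p)
    np.testing.assert_array_equal(s1.H.data, s2.H.data)


def test_encoder_handles_edgeless_graph():
    cfg = small_config()
    enc = GTEncoder(cfg, np.random.default_rng(1))
    enc.eval()
    H = np.random.default_rng(0).standard_normal((3, cfg.d_h))
    E = np.zeros((0, cfg.d_e))
    out = enc(Tensor(H), Tensor(E), np.zeros((0, 2), dtype=np.int64))
    assert out.H.shape == (3, cfg.d_p) and np.isfinite(out.H.data).all()


def test_no_gt_flag_reduces_to_input_projection():
    cfg = small_config(no_gt=True)
    enc = GTEncoder(cfg, np.random.default_rng(6))
    enc.eval()
    rng = np.random.default_rng(7)
    H, E, edge_index = random_graph(rng, 8, cfg)
    out = enc(Tensor(H), Tensor(E), edge_index)
    proj = InputProjection.__call__(enc.project, Tensor(H), Tensor(E))
    np.testing.assert_allclose(out.H.data, proj.H.data)


def test_input_projection_rejects_wrong_dims():
    cfg = small_config()
    proj = InputProjection(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError, match="input dims"):
        proj(Tensor(np.zeros((4, cfg.d_h + 1))), Tensor(np.zeros((2, cfg.d_e))))


def test_layer_gradients_flow_to_inputs():
    cfg = small_config()
    rng = np.random.default_rng(11)
    layer = GTLayer(cfg, np.random.default_rng(12))
    layer.eval()
    coords = random_backbone(rng, 7)
    edge_index = build_contact_map(coords, 8.0)
    H = Tensor(rng.standard_normal((7, cfg.d_p)), requires_grad=True)
    E = Tensor(rng.standard_normal((edge_index.shape[0], cfg.d_p)),
               requires_grad=True)
    out = layer(_state(H, E), edge_index)
    (out.H.sum() + out.E.sum()).backward()
    assert H.grad is not None and np.abs(H.grad).sum() > 0
    assert E.grad is not None and np.abs(E.grad).sum() > 0
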