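"""Encoder/decoder checks against a direct dense evaluation of the layer
equations, plus the structural invariants (attention normalization, weight
tying, permutation equivariance)."""

import numpy as np
import pytest

import spotgae as sg
from spotgae.model import DGATLayerParams, attention_scores


def dense_forward(A, X, params):
    """Independent oracle: explicit loops over neighbor sets.

    A is a dense 0/1 adjacency (no self-loops); neighborhoods N_i are the
    stored neighbors plus i itself.  Attention layers score
    e_ij = v . sigmoid(W0 h_i + W1 h_j) (weights in the 'W h' column
    orientation), softmax over N_i; the final layer is the unweighted sum.
    The decoder reverses the stack with transposed weights and reuses the
    encoder attention.
    """
    n = A.shape[0]
    nbrs = [sorted(set(np.flatnonzero(A[i]).tolist()) | {i}) for i in range(n)]
    sig = lambda t: 1.0 / (1.0 + np.exp(-t))
    elu = lambda t: np.where(t > 0, t, np.expm1(t))

    H = X.copy()
    atts = []
    L = len(params.layers)
    for k, layer in enumerate(params.layers, start=1):
        W0c = layer.W0.T  # column orientation: maps h (d_in,) -> (d_out,)
        new = np.zeros((n, layer.d_out))
        if layer.has_attention:
            W1c = layer.W1.T
            att = {}
            for i in range(n):
                e = np.array([layer.v @ sig(W0c @ H[i] + W1c @ H[j])
                              for j in nbrs[i]])
                w = np.exp(e - e.max())
                w /= w.sum()
                for j, wij in zip(nbrs[i], w):
                    att[(i, j)] = wij
                new[i] = sum(wij * (W0c @ H[j])
                             for j, wij in zip(nbrs[i], w))
            atts.append(att)
        else:
            for i in range(n):
                new[i] = sum(W0c @ H[j] for j in nbrs[i])
        H = elu(new)
    # decoder: transposed weights, reversed order, reused attention
    D = H.copy()
    for k in range(L, 1, -1):
        Wd = params.layers[k - 1].W0  # (d_{k-1} x d_k) == encoder W0^T
        att = atts[k - 2]
        new = np.zeros((n, Wd.shape[0]))
        for i in range(n):
            new[i] = sum(att[(i, j)] * (Wd @ D[j]) for j in nbrs[i])
        D = elu(new)
    Wd = params.layers[0].W0
    Z = elu(np.array([sum(Wd @ D[j] for j in nbrs[i]) for i in range(n)]))
    return H, atts, Z


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_encode_decode_match_dense_oracle(seed, rng):
    """On <=5-node graphs the sparse implementation reproduces the dense
    hand evaluation to 1e-10."""
    local = np.random.default_rng(seed)
    n, d_in = 5, 3
    params = sg.init_params(d_in, (4, 2), local)
    X = local.normal(size=(n, d_in))
    edges = {(0, 1), (1, 2), (2, 3), (0, 4), (1, 4)}
    g = sg.SpatialNeighborGraph(n, edges, "knn")
    A = g.adjacency().toarray()

    H_ref, atts_ref, Z_ref = dense_forward(A, X, params)
    H, att = sg.encode(g, X, params)
    np.testing.assert_allclose(H, H_ref, atol=1e-10)
    got = {(i, j): w for i, j, w in zip(att.src, att.dst, att.weights[1])}
    for key, val in atts_ref[0].items():
        assert abs(got[key] - val) < 1e-10
    Z = sg.decode(g, H, params, att)
    np.testing.assert_allclose(Z, Z_ref, atol=1e-10)


def test_attention_two_node_hand_example():
    """x=(1,2), scalar weights 1: att_aa = exp(s(2))/(exp(s(2))+exp(s(3)))."""
    layer = DGATLayerParams(W0=np.array([[1.0]]), W1=np.array([[1.0]]),
                            v=np.array([1.0]), has_attention=True)
    g = sg.SpatialNeighborGraph(2, {(0, 1)}, "knn")
    rec = attention_scores(np.array([[1.0], [2.0]]), g, layer)
    w = {(i, j): v for i, j, v in zip(rec.src, rec.dst, rec.weights[1])}
    assert w[(0, 0)] == pytest.approx(0.4821, abs=1e-4)
    assert w[(0, 1)] == pytest.approx(0.5179, abs=1e-4)
    # downstream hidden state: ELU(0.4821*1 + 0.5179*2) ~ 1.5179
    h_a = w[(0, 0)] * 1.0 + w[(0, 1)] * 2.0
    assert h_a == pytest.approx(1.5179, abs=1e-4)


def test_attention_uniform_when_v_zero(rng):
    """v = 0 makes all scores equal: att is uniform over N_i."""
    layer = DGATLayerParams(W0=rng.normal(size=(3, 4)),
                            W1=rng.normal(size=(3, 4)),
                            v=np.zeros(4), has_attention=True)
    g = sg.SpatialNeighborGraph(4, {(0, 1), (0, 2), (0, 3)}, "knn")
    rec = attention_scores(rng.normal(size=(4, 3)), g, layer)
    w = {(i, j): v for i, j, v in zip(rec.src, rec.dst, rec.weights[1])}
    for j in range(4):  # node 0 has N_0 = {0,1,2,3}
        assert w[(0, j)] == pytest.approx(0.25)


def test_isolated_node_self_attention_is_one(tiny_graph, rng):
    layer = DGATLayerParams(W0=rng.normal(size=(2, 3)),
                            W1=rng.normal(size=(2, 3)),
                            v=rng.normal(size=3), has_attention=True)
    rec = attention_scores(rng.normal(size=(5, 2)), tiny_graph, layer)
    w = {(i, j): v for i, j, v in zip(rec.src, rec.dst, rec.weights[1])}
    assert w[(4, 4)] == pytest.approx(1.0)


def test_attention_rows_sum_to_one(tiny_graph, rng):
    params = sg.init_params(3, (4, 2), rng)
    X = rng.normal(size=(5, 3))
    _, att = sg.encode(tiny_graph, X, params)
    sums = np.zeros(5)
    np.add.at(sums, att.src, att.weights[1])
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    assert np.all(att.weights[1] >= 0) and np.all(att.weights[1] <= 1)


def test_single_isolated_node_identity_layer():
    """One node, one layer, W0 = I: h = ELU(x)."""
    params = sg.DGATParams(
        [sg.DGATLayerParams(np.eye(3), None, None, False)],
        np.zeros(3), np.zeros(3))
    g = sg.SpatialNeighborGraph(1, set(), "knn")
    x = np.array([[0.5, -1.2, 0.0]])
    H, _ = sg.encode(g, x, params)
    np.testing.assert_allclose(H, np.where(x > 0, x, np.expm1(x)), atol=1e-12)


def test_zero_input_gives_zero_embedding(tiny_graph, rng):
    params = sg.init_params(3, (4, 2), rng)
    H, att = sg.encode(tiny_graph, np.zeros((5, 3)), params)
    np.testing.assert_allclose(H, 0.0, atol=1e-12)
    Z = sg.decode(tiny_graph, np.zeros((5, 2)), params, att)
    np.testing.assert_allclose(Z, 0.0, atol=1e-12)


def test_decoder_weights_are_exact_transposes(rng):
    """No decoder-only weights exist: trainable state is encoder weights,
    attention vectors, and the two tokens."""
    params = sg.init_params(6, (4, 2), rng)
    arrays = params.trainable_arrays()
    # 2 layers: W0 x2, W1 + v on layer 1, plus 2 tokens
    assert len(arrays) == 6
    # the decode path consumes layer.W0 transposed and nothing else; verify
    # numerically: perturbing W0 changes the decode output, with no separate
    # decoder parameter to perturb
    g = sg.SpatialNeighborGraph(3, {(0, 1), (1, 2)}, "knn")
    X = rng.normal(size=(3, 6))
    H, att = sg.encode(g, X, params)
    Z1 = sg.decode(g, H, params, att)
    params.layers[0].W0 += 0.1
    Z2 = sg.decode(g, H, params, att)
    assert not np.allclose(Z1, Z2)


def test_permutation_equivariance(rng):
    """Permuting spots and the graph consistently permutes H and Z."""
    n, d_in = 6, 4
    params = sg.init_params(d_in, (3, 2), rng)
    X = rng.normal(size=(n, d_in))
    edges = {(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)}
    g = sg.SpatialNeighborGraph(n, edges, "knn")
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    g_p = sg.SpatialNeighborGraph(
        n, {(min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in edges},
        "knn")
    H, att = sg.encode(g, X, params)
    Hp, att_p = sg.encode(g_p, X[perm], params)
    np.testing.assert_allclose(Hp, H[perm], atol=1e-10)
    Z = sg.decode(g, H, params, att)
    Zp = sg.decode(g_p, Hp, params, att_p)
    np.testing.assert_allclose(Zp, Z[perm], atol=1e-10)


def test_forward_dual_shapes_and_degenerate_case(rng):
    ds, _ = sg.make_dataset(sg.standard_small(rows=6, cols=6, n_genes=40))
    pp = sg.preprocess(ds, sg.PreprocessConfig())
    g = sg.build_sng_knn(pp.coords, 6)
    params = sg.init_params(pp.n_genes, (16, 8), rng)
    out = sg.forward_dual(g, pp.expr, params, rng=rng)
    assert out.H.shape == (36, 8)
    assert out.Z0.shape == out.Z1.shape == (36, pp.n_genes)
    # no corruption -> both views identical through the tied decoder
    out0 = sg.forward_dual(g, pp.expr, params, mask_ratio=0.0,
                           replace_ratio=0.0, remask_ratio=0.0, rng=rng)
    np.testing.assert_array_equal(out0.Z0, out0.Z1)
    np.testing.assert_array_equal(out0.X_masked, pp.expr)


def test_dual_remask_views_differ(rng):
    """Two independent 50% remask draws at N=1000 differ essentially surely."""
    p0 = sg.draw_remask_plan(1000, 0.5, rng)
    p1 = sg.draw_remask_plan(1000, 0.5, rng)
    assert not np.array_equal(p0.remask_set, p1.remask_set)


def test_latent_dimension_default_dims(rng):
    params = sg.init_params(100, (512, 30), rng)
    assert params.d_latent == 30
    g = sg.SpatialNeighborGraph(3, {(0, 1), (1, 2)}, "knn")
    H, _ = sg.encode(g, rng.normal(size=(3, 100)), params)
    assert H.shape == (3, 30)


def test_export_layer_without_attention_errors(tiny_graph, rng):
    params = sg.init_params(3, (4, 2), rng)
    X = rng.normal(size=(5, 3))
    _, att = sg.encode(tiny_graph, X, params)
    with pytest.raises(ValueError, match="valid layers"):
        att.layer_weights(2)
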