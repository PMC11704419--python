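"""Dynamic graph-attention encoder with a weight-tied decoder.

Per attention layer k, the score for neighbor j of query node i is

    e_ij = v_k' * sigmoid(W0_k h_i + W1_k h_j)

(activation before the scoring projection, so the neighbor ranking can change
with the query node), normalized by a softmax over N_i — the stored neighbors
of i plus i itself.  Hidden states update as

    h_i^(k) = ELU( sum_{j in N_i} att_ij^(k) * W0_k h_j^(k-1) )

and the final encoder layer drops the attention weighting.  The decoder runs
the stack in reverse with the *transposed* encoder weights and reuses the
encoder's attention coefficients verbatim; its last step is again unweighted.
No bias terms anywhere; ELU uses alpha = 1.

Weights are stored input-dim x output-dim, i.e. the transpose of the
conventional "W h" orientation, so hidden states are row vectors and layers
compute ``H @ W``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .graph import SpatialNeighborGraph
from .masking import MaskPlan, RemaskPlan, apply_mask, apply_remask

__all__ = [
    "DGATLayerParams", "DGATParams", "AttentionRecord", "DualViewOutput",
    "init_params", "attention_scores", "encode", "decode", "forward_dual",
    "save_params", "load_params",
]


@dataclass
class DGATLayerParams:
    """One layer's trainable state; W1 and v exist only on attention layers.

    Shapes: W0 is (d_in, d_out); W1 likewise; v is (d_out,).  The decoder
    never owns weights — it reuses these arrays transposed.
    """
    W0: np.ndarray
    W1: np.ndarray | None
    v: np.ndarray | None
    has_attention: bool

    @property
    def d_in(self) -> int:
        return self.W0.shape[0]

    @property
    def d_out(self) -> int:
        return self.W0.shape[1]


@dataclass
class DGATParams:
    """Complete trainable state: layer stack plus the two mask tokens."""
    layers: list[DGATLayerParams]
    mask_token: np.ndarray      # input-dimension vector, replaces masked rows
    remask_token: np.ndarray    # latent-dimension vector, replaces remasked rows

    def __post_init__(self):
        if not self.layers:
            raise ValueError("need at least one layer")
        if self.layers[-1].has_attention:
            raise ValueError("final encoder layer must not use attention")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.d_out != b.d_in:
                raise ValueError("inconsistent layer dimensions")
        if self.mask_token.shape != (self.layers[0].d_in,):
            raise ValueError("mask token must have input dimension")
        if self.remask_token.shape != (self.layers[-1].d_out,):
            raise ValueError("remask token must have latent dimension")

    @property
    def d_in(self) -> int:
        return self.layers[0].d_in

    @property
    def d_latent(self) -> int:
        return self.layers[-1].d_out

    def trainable_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.append(layer.W0)
            if layer.has_attention:
                out += [layer.W1, layer.v]
        out += [self.mask_token, self.remask_token]
        return out


@dataclass
class AttentionRecord:
    """Per attention layer: directed (src, dst incl. self) pairs and the
    softmax-normalized weights.  Rows (fixed src) sum to 1."""
    src: np.ndarray
    dst: np.ndarray
    weights: dict = field(default_factory=dict)  # layer index (1-based) -> (E,) array

    def layer_weights(self, layer: int) -> np.ndarray:
        if layer not in self.weights:
            raise ValueError(
                f"layer {layer} has no attention; valid layers: "
                f"{sorted(self.weights)}")
        return self.weights[layer]


@dataclass
class DualViewOutput:
    X_masked: np.ndarray
    H: np.ndarray
    H_remasked0: np.ndarray
    H_remasked1: np.ndarray
    Z0: np.ndarray
    Z1: np.ndarray
    mask_plan: MaskPlan
    remask_plans: tuple
    attention: AttentionRecord


def init_params(d_in: int, dims: list[int] | tuple = (512, 30),
                rng_seed=0) -> DGATParams:
    """Glorot-uniform weights; zero-initialized mask/remask tokens."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    widths = [d_in] + list(dims)
    layers = []
    n_layers = len(dims)
    for k in range(n_layers):
        fan_in, fan_out = widths[k], widths[k + 1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W0 = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        has_att = k < n_layers - 1
        if has_att:
            W1 = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            v = rng.uniform(-limit, limit, size=fan_out)
            layers.append(DGATLayerParams(W0, W1, v, True))
        else:
            layers.append(DGATLayerParams(W0, None, None, False))
    return DGATParams(layers, np.zeros(d_in), np.zeros(dims[-1]))


def save_params(params: DGATParams, path) -> None:
    arrays = {"mask_token": params.mask_token,
              "remask_token": params.remask_token,
              "n_layers": np.array(len(params.layers))}
    for k, layer in enumerate(params.layers, start=1):
        arrays[f"W0_{k}"] = layer.W0
        if layer.has_attention:
            arrays[f"W1_{k}"] = layer.W1
            arrays[f"v_{k}"] = layer.v
    np.savez(path, **arrays)


def load_params(path) -> DGATParams:
    with np.load(path) as z:
        n_layers = int(z["n_layers"])
        layers = []
        for k in range(1, n_layers + 1):
            if f"W1_{k}" in z:
                layers.append(DGATLayerParams(z[f"W0_{k}"], z[f"W1_{k}"],
                                              z[f"v_{k}"], True))
            else:
                layers.append(DGATLayerParams(z[f"W0_{k}"], None, None, False))
        return DGATParams(layers, z["mask_token"], z["remask_token"])


# ---------------------------------------------------------------------------
# tensor-level forward passes (shared by training and the public NumPy API)
# ---------------------------------------------------------------------------

def _segment_softmax(e: Tensor, src: np.ndarray, n: int) -> Tensor:
    """Softmax of edge scores within each src group, max-stabilized."""
    m = np.full(n, -np.inf)
    np.maximum.at(m, src, e.value)
    shifted = ag.sub(e, ag.constant(m[src]))
    ex = ag.exp(shifted)
    denom = ag.gather(ag.segment_sum(ex, src, n), src)
    return ag.div(ex, denom)


def _encode_t(Xt: Tensor, params: DGATParams, src: np.ndarray,
              dst: np.ndarray, n: int,
              layer_tensors: list[dict]) -> tuple[Tensor, dict]:
    """Run the encoder on tensors; returns latent H and attention tensors
    keyed by 1-based layer index."""
    H = Xt
    att_tensors: dict[int, Tensor] = {}
    for k, (layer, lt) in enumerate(zip(params.layers, layer_tensors), start=1):
        HW0 = ag.matmul(H, lt["W0"])
        if layer.has_attention:
            HW1 = ag.matmul(H, lt["W1"])
            s = ag.sigmoid(ag.add(ag.gather(HW0, src), ag.gather(HW1, dst)))
            e = ag.matmul(s, lt["v"])
            att = _segment_softmax(e, src, n)
            att_tensors[k] = att
            msg = ag.segment_sum(
                ag.mul(ag.reshape(att, (-1, 1)), ag.gather(HW0, dst)), src, n)
        else:
            msg = ag.segment_sum(ag.gather(HW0, dst), src, n)
        H = ag.elu(msg)
        if not np.all(np.isfinite(H.value)):
            raise FloatingPointError(f"non-finite encoder output at layer {k}")
    return H, att_tensors


def _decode_t(Ht: Tensor, params: DGATParams, src: np.ndarray,
              dst: np.ndarray, n: int, layer_tensors: list[dict],
              att_tensors: dict) -> Tensor:
    """Run the tied decoder: reversed layers, transposed weights, reused
    attention; the last step (back to input space) is unweighted."""
    L = len(params.layers)
    H = Ht
    for k in range(L, 1, -1):  # decoder step k maps layer k -> k-1
        W_dec = ag.transpose(layer_tensors[k - 1]["W0"])
        HW = ag.matmul(H, W_dec)
        att = att_tensors[k - 1]  # encoder layer k-1 attention, reused
        msg = ag.segment_sum(
            ag.mul(ag.reshape(att, (-1, 1)), ag.gather(HW, dst)), src, n)
        H = ag.elu(msg)
    HW = ag.matmul(H, ag.transpose(layer_tensors[0]["W0"]))
    Z = ag.elu(ag.segment_sum(ag.gather(HW, dst), src, n))
    return Z


def wrap_layer_tensors(params: DGATParams,
                       trainable: bool) -> list[dict]:
    make = ag.parameter if trainable else ag.constant
    out = []
    for layer in params.layers:
        d = {"W0": make(layer.W0)}
        if layer.has_attention:
            d["W1"] = make(layer.W1)
            d["v"] = make(layer.v)
        out.append(d)
    return out


def _attention_record(src, dst, att_tensors) -> AttentionRecord:
    return AttentionRecord(src=src, dst=dst,
                           weights={k: t.value.copy()
                                    for k, t in att_tensors.items()})


# ---------------------------------------------------------------------------
# public NumPy-level API
# ---------------------------------------------------------------------------

def attention_scores(H_prev: np.ndarray, graph: SpatialNeighborGraph,
                     layer: DGATLayerParams) -> AttentionRecord:
    """Attention coefficients of a single layer on given inputs."""
    if not layer.has_attention:
        raise ValueError("layer has no attention mechanism")
    src, dst = graph.directed_with_self()
    Ht = ag.constant(np.asarray(H_prev, dtype=float))
    HW0 = ag.matmul(Ht, ag.constant(layer.W0))
    HW1 = ag.matmul(Ht, ag.constant(layer.W1))
    s = ag.sigmoid(ag.add(ag.gather(HW0, src), ag.gather(HW1, dst)))
    e = ag.matmul(s, ag.constant(layer.v))
    att = _segment_softmax(e, src, graph.n)
    return AttentionRecord(src=src, dst=dst, weights={1: att.value.copy()})


def encode(graph: SpatialNeighborGraph, X_in: np.ndarray,
           params: DGATParams) -> tuple[np.ndarray, AttentionRecord]:
    """Encoder forward pass on plain arrays (no gradients)."""
    X_in = np.asarray(X_in, dtype=float)
    if X_in.shape[1] != params.d_in:
        raise ValueError(f"input has {X_in.shape[1]} features, "
                         f"model expects {params.d_in}")
    src, dst = graph.directed_with_self()
    lt = wrap_layer_tensors(params, trainable=False)
    H, att_t = _encode_t(ag.constant(X_in), params, src, dst, graph.n, lt)
    return H.value, _attention_record(src, dst, att_t)


def decode(graph: SpatialNeighborGraph, H_remasked: np.ndarray,
           params: DGATParams, att: AttentionRecord) -> np.ndarray:
    """Tied-decoder forward pass on plain arrays, reusing encoder attention."""
    H_remasked = np.asarray(H_remasked, dtype=float)
    if H_remasked.shape[1] != params.d_latent:
        raise ValueError("latent dimension mismatch")
    src, dst = graph.directed_with_self()
    if len(src) != len(att.src):
        raise ValueError("attention record does not match graph")
    lt = wrap_layer_tensors(params, trainable=False)
    att_t = {k: ag.constant(w) for k, w in att.weights.items()}
    Z = _decode_t(ag.constant(H_remasked), params, src, dst, graph.n, lt, att_t)
    return Z.value


def forward_dual(graph: SpatialNeighborGraph, X: np.ndarray,
                 params: DGATParams, mask_ratio: float = 0.5,
                 replace_ratio: float = 0.05, remask_ratio: float = 0.5,
                 rng=0) -> DualViewOutput:
    """One full corrupted forward pass: MASK -> encode -> two independent
    REMASK draws -> two tied decodes sharing the encoder attention."""
    from .masking import draw_mask_plan, draw_remask_plan
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    # fixed draw order from one stream: mask, remask view 0, remask view 1
    plan = draw_mask_plan(n, mask_ratio, replace_ratio, rng)
    rplan0 = draw_remask_plan(n, remask_ratio, rng)
    rplan1 = draw_remask_plan(n, remask_ratio, rng)

    X_masked = apply_mask(X, plan, params.mask_token)
    H, att = encode(graph, X_masked, params)
    H0 = apply_remask(H, rplan0, params.remask_token)
    H1 = apply_remask(H, rplan1, params.remask_token)
    Z0 = decode(graph, H0, params, att)
    Z1 = decode(graph, H1, params, att)
    return DualViewOutput(X_masked, H, H0, H1, Z0, Z1, plan,
                          (rplan0, rplan1), att)
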