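"""Scaled-cosine-error losses, the Adam training loop, and inference passes.

The objective per epoch is

    Loss = L_sce0 + L_sce1 + L_wd

where L_sce0 is the mean of (1 - cos(x_i, z0_i))^gamma over masked spots
(noise correction view), L_sce1 the same over kept spots against the second
view (detail recovery), and L_wd an explicit L2 penalty over all W0/W1
matrices.  Because the penalty is explicit, the optimizer's own decay is
zero — the weights are never penalized twice.

Inference runs the uncorrupted input through the encoder (and one tied
decode for denoising); no masking, so embeddings are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ag
from .graph import SpatialNeighborGraph
from .io import SpatialDataset
from .masking import MaskPlan, draw_mask_plan, draw_remask_plan
from .model import (DGATParams, _decode_t, _encode_t, _attention_record,
                    init_params, wrap_layer_tensors)

__all__ = [
    "TrainingConfig", "LossBreakdown", "sce", "total_loss", "fit",
    "get_latent", "get_denoised",
]

_EPS = 1e-12


@dataclass
class TrainingConfig:
    dims: tuple = (512, 30)
    lr: float = 0.001
    weight_decay: float = 0.001
    gamma: float = 2.0
    epochs: int = 500
    mask_ratio: float = 0.5
    replace_ratio: float = 0.05
    remask_ratio: float = 0.5
    seed: int = 0
    device: str = "cpu"      # hint only; computation is NumPy throughout
    keep_only: bool = False  # score only the kept-node view (no masked-view loss)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (1.0 <= self.gamma <= 3.0):
            warnings.warn(f"gamma={self.gamma} outside the usual [1, 3] range")


@dataclass
class LossBreakdown:
    L_sce0: float
    L_sce1: float
    L_wd: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.total is None:
            self.total = self.L_sce0 + self.L_sce1 + self.L_wd


def sce(x_rows: np.ndarray, z_rows: np.ndarray, gamma: float) -> float:
    """Mean over paired rows of (1 - cosine similarity)^gamma.

    Zero-norm rows contribute cosine 0 (epsilon guard) with a warning.
    Scale-invariant per row; value lies in [0, 2**gamma].
    """
    x = np.atleast_2d(np.asarray(x_rows, dtype=float))
    z = np.atleast_2d(np.asarray(z_rows, dtype=float))
    if x.shape != z.shape or x.shape[0] < 1:
        raise ValueError("x_rows and z_rows must be paired, nonempty")
    xn = np.linalg.norm(x, axis=1)
    zn = np.linalg.norm(z, axis=1)
    if np.any(xn == 0) or np.any(zn == 0):
        warnings.warn("zero-norm row in cosine loss; treated as cosine 0")
    cos = (x * z).sum(axis=1) / (xn * zn + _EPS)
    return float(np.mean((1.0 - cos) ** gamma))


def total_loss(X: np.ndarray, Z0: np.ndarray, Z1: np.ndarray,
               plan: MaskPlan, params: DGATParams,
               weight_decay: float = 0.001, gamma: float = 2.0,
               keep_only: bool = False) -> LossBreakdown:
    """Dual-view SCE plus the explicit L2 term over all W0/W1 matrices."""
    masked, keep = plan.masked_set, plan.keep_set
    if len(masked) == 0 and not keep_only:
        raise ValueError("masked set is empty; request keep_only mode or "
                         "use mask_ratio > 0")
    l0 = 0.0 if (keep_only or len(masked) == 0) else sce(
        X[masked], Z0[masked], gamma)
    l1 = sce(X[keep], Z1[keep], gamma) if len(keep) else 0.0
    lwd = 0.0
    for layer in params.layers:
        lwd += float((layer.W0 ** 2).sum())
        if layer.has_attention:
            lwd += float((layer.W1 ** 2).sum())
    lwd *= weight_decay
    return LossBreakdown(l0, l1, lwd)


# ---------------------------------------------------------------------------
# tensor-level loss pieces
# ---------------------------------------------------------------------------

def _sce_t(Z: ag.Tensor, X: np.ndarray, idx: np.ndarray, gamma: float):
    z = ag.gather(Z, idx)
    x = X[idx]
    xn = np.linalg.norm(x, axis=1)
    num = ag.tsum(ag.mul(ag.constant(x), z), axis=1)
    zn = ag.sqrt(ag.add(ag.tsum(ag.mul(z, z), axis=1),
                        ag.constant(_EPS ** 2)))
    den = ag.add(ag.mul(ag.constant(xn), zn), ag.constant(_EPS))
    cos = ag.div(num, den)
    return ag.tmean(ag.power(ag.sub(ag.constant(np.ones(len(idx))), cos), gamma))


def _corrupt_t(base: np.ndarray, indicator: np.ndarray, token: ag.Tensor):
    """base (token rows zeroed) + indicator-column * token-row broadcast."""
    return ag.add(ag.constant(base),
                  ag.mul(ag.constant(indicator[:, None]),
                         ag.reshape(token, (1, -1))))


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.arrays = arrays
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2 = self.betas
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit(dataset: SpatialDataset, graph: SpatialNeighborGraph,
        cfg: TrainingConfig | None = None) -> tuple[DGATParams, list[LossBreakdown]]:
    """Self-supervised training: fresh mask/remask plans every epoch, dual
    decode, SCE + L2 loss, Adam step.  Deterministic for a fixed seed."""
    cfg = cfg or TrainingConfig()
    X = np.asarray(dataset.expr, dtype=float)
    n, d_in = X.shape
    if graph.n != n:
        raise ValueError(f"graph has {graph.n} nodes, dataset {n} spots")
    if cfg.mask_ratio == 0 and not cfg.keep_only:
        raise ValueError("mask_ratio=0 leaves the masked-view loss undefined; "
                         "set keep_only=True for a kept-node-only objective")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(d_in, cfg.dims, rng)
    arrays = params.trainable_arrays()
    opt = _Adam(arrays, cfg.lr)
    src, dst = graph.directed_with_self()
    log: list[LossBreakdown] = []

    for epoch in range(cfg.epochs):
        # fixed draw order from one shared stream per epoch
        plan = draw_mask_plan(n, cfg.mask_ratio, cfg.replace_ratio, rng)
        rplan0 = draw_remask_plan(n, cfg.remask_ratio, rng)
        rplan1 = draw_remask_plan(n, cfg.remask_ratio, rng)

        layer_t = wrap_layer_tensors(params, trainable=True)
        mask_tok = ag.parameter(params.mask_token)
        remask_tok = ag.parameter(params.remask_token)

        base = X.copy()
        token_rows = plan.token_rows
        ind = np.zeros(n)
        if len(token_rows):
            base[token_rows] = 0.0
            ind[token_rows] = 1.0
        for tgt, srcspot in plan.replace_pairs:
            base[tgt] = X[srcspot]
        Xt = _corrupt_t(base, ind, mask_tok)

        H, att_t = _encode_t(Xt, params, src, dst, n, layer_t)

        views = []
        for rplan in (rplan0, rplan1):
            ind_v = np.zeros(n)
            ind_v[rplan.remask_set] = 1.0
            Ht = ag.add(ag.mul(H, ag.constant((1.0 - ind_v)[:, None])),
                        ag.mul(ag.constant(ind_v[:, None]),
                               ag.reshape(remask_tok, (1, -1))))
            views.append(_decode_t(Ht, params, src, dst, n, layer_t, att_t))
        Z0, Z1 = views

        sce0_t = (_sce_t(Z0, X, plan.masked_set, cfg.gamma)
                  if (not cfg.keep_only and len(plan.masked_set)) else None)
        sce1_t = (_sce_t(Z1, X, plan.keep_set, cfg.gamma)
                  if len(plan.keep_set) else None)
        parts = [p for p in (sce0_t, sce1_t) if p is not None]
        wd_terms = []
        for lt, layer in zip(layer_t, params.layers):
            wd_terms.append(ag.tsum(ag.mul(lt["W0"], lt["W0"])))
            if layer.has_attention:
                wd_terms.append(ag.tsum(ag.mul(lt["W1"], lt["W1"])))
        lwd = ag.mul(ag.constant(cfg.weight_decay), wd_terms[0])
        for t in wd_terms[1:]:
            lwd = ag.add(lwd, ag.mul(ag.constant(cfg.weight_decay), t))

        loss = lwd
        for p in parts:
            loss = ag.add(loss, p)

        if not np.isfinite(loss.value):
            raise FloatingPointError(f"loss is not finite at epoch {epoch}")

        loss.backward()

        tensors = []
        for lt, layer in zip(layer_t, params.layers):
            tensors.append(lt["W0"])
            if layer.has_attention:
                tensors += [lt["W1"], lt["v"]]
        tensors += [mask_tok, remask_tok]
        grads = [t.grad if t.grad is not None else np.zeros_like(t.value)
                 for t in tensors]
        opt.step(grads)

        log.append(LossBreakdown(
            float(sce0_t.value) if sce0_t is not None else 0.0,
            float(sce1_t.value) if sce1_t is not None else 0.0,
            float(lwd.value)))
    return params, log


def get_latent(dataset: SpatialDataset, graph: SpatialNeighborGraph,
               params: DGATParams) -> np.ndarray:
    """Latent embeddings of the uncorrupted input (deterministic)."""
    from .model import encode
    H, _ = encode(graph, np.asarray(dataset.expr, dtype=float), params)
    return H


def get_denoised(dataset: SpatialDataset, graph: SpatialNeighborGraph,
                 params: DGATParams) -> np.ndarray:
    """Reconstructed expression from one tied decode of the clean latent."""
    from .model import encode, decode
    X = np.asarray(dataset.expr, dtype=float)
    H, att = encode(graph, X, params)
    return decode(graph, H, params, att)
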