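"""Clustering of latent embeddings and evaluation metrics.

Spatial domains are called by model-based clustering: a Gaussian mixture with
a shared (tied) covariance across components, k-means++ seeded, with the
component count fixed to the annotation count.  Agreement with ground truth
uses ARI / NMI / FMS.  Batch mixing is scored by iLISI — the per-spot inverse
Simpson's index of batch proportions in a perplexity-weighted embedding
neighborhood (1 = unmixed, B = perfectly mixed among B batches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .model import AttentionRecord

__all__ = [
    "ClusterResult", "cluster_latent", "ari", "nmi", "fms", "ilisi",
    "calinski_harabasz", "davies_bouldin", "export_attention",
    "evaluate_clustering",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # N integers in 1..K
    K: int
    seed: int
    model_kind: str


def cluster_latent(H: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """Shared-covariance Gaussian-mixture clustering of embeddings."""
    H = np.asarray(H, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > H.shape[0]:
        raise ValueError("k exceeds number of spots")
    if np.allclose(H.var(axis=0), 0):
        raise ValueError("embeddings have zero variance in every dimension; "
                         "nothing to cluster")
    # full k-means initialization (itself k-means++ seeded); bare k-means++
    # point seeding can hand EM a degenerate start on anisotropic latents
    gm = GaussianMixture(n_components=k, covariance_type="tied",
                         init_params="kmeans", n_init=5,
                         max_iter=300, reg_covar=1e-6, random_state=seed)
    labels = gm.fit_predict(H) + 1
    return ClusterResult(labels=labels, K=k, seed=seed,
                         model_kind="gaussian-mixture/tied-covariance/kmeans-init")


def _check_pair(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label length mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def ari(pred, truth) -> float:
    pred, truth = _check_pair(pred, truth)
    return float(skm.adjusted_rand_score(truth, pred))


def nmi(pred, truth) -> float:
    pred, truth = _check_pair(pred, truth)
    return float(skm.normalized_mutual_info_score(truth, pred))


def fms(pred, truth) -> float:
    pred, truth = _check_pair(pred, truth)
    return float(skm.fowlkes_mallows_score(truth, pred))


def calinski_harabasz(H, labels) -> float:
    return float(skm.calinski_harabasz_score(np.asarray(H), np.asarray(labels)))


def davies_bouldin(H, labels) -> float:
    return float(skm.davies_bouldin_score(np.asarray(H), np.asarray(labels)))


def ilisi(H: np.ndarray, batch, perplexity: float = 30.0) -> np.ndarray:
    """Per-spot integration local inverse Simpson's index.

    For each spot, neighbor weights over its 3*perplexity nearest neighbors
    in embedding space are calibrated to the target perplexity (Gaussian
    kernel, binary search on the bandwidth, as in the metric's original
    formulation); the index is 1 / sum_b p_b^2 over batch proportions p_b.
    Values lie in [1, n_batches].
    """
    H = np.asarray(H, dtype=float)
    batch = np.asarray(batch)
    cats, bidx = np.unique(batch, return_inverse=True)
    n_batches = len(cats)
    n = H.shape[0]
    if n_batches < 2:
        warnings.warn("single batch: iLISI is 1 everywhere")
        return np.ones(n)
    k = int(min(3 * perplexity, n - 1))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(H)
    dist, idx = nn.kneighbors(H)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist ** 2
    log_u = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        beta_lo, beta_hi, beta = 0.0, np.inf, 1.0
        di = d2[i] - d2[i].min()
        for _ in range(64):
            w = np.exp(-beta * di)
            s = w.sum()
            p = w / s
            h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
            if abs(h - log_u) < 1e-5:
                break
            if h > log_u:       # too flat -> sharpen
                beta_lo = beta
                beta = beta * 2 if beta_hi == np.inf else (beta + beta_hi) / 2
            else:
                beta_hi = beta
                beta = (beta + beta_lo) / 2
        props = np.bincount(bidx[idx[i]], weights=p, minlength=n_batches)
        out[i] = 1.0 / np.sum(props ** 2)
    return out


def export_attention(att: AttentionRecord, coords: np.ndarray, layer: int,
                     spot_ids=None) -> pd.DataFrame:
    """Directed edge table (src, dst, positions, weight) for one attention
    layer, for plotting microenvironment heterogeneity; self-loops flagged."""
    w = att.layer_weights(layer)  # raises with valid layers listed
    coords = np.asarray(coords)
    src, dst = att.src, att.dst
    ids = (np.asarray(spot_ids) if spot_ids is not None
           else np.arange(len(coords)).astype(str))
    return pd.DataFrame({
        "src": ids[src], "dst": ids[dst],
        "x_src": coords[src, 0], "y_src": coords[src, 1],
        "x_dst": coords[dst, 0], "y_dst": coords[dst, 1],
        "layer": layer,
        "weight": w,
        "self_loop": src == dst,
    })


def evaluate_clustering(pred, truth) -> dict:
    return {"ari": ari(pred, truth), "nmi": nmi(pred, truth),
            "fms": fms(pred, truth)}
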