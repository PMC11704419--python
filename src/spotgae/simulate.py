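"""Synthetic spatial-transcriptomics fixtures.

Emulates the data model the method assumes: spots on a hexagonal (Visium-like)
or square lattice, spatially coherent expression domains (horizontal bands —
cortical-layer-like — or Voronoi blobs), negative-binomial counts with
domain-programmed fold changes, technical dropout (independent zeroing), and
multi-slice stacks with per-slice per-gene multiplicative (log-normal) batch
factors.

Study conditions are fixed by the generator defaults: domain-informative genes
carry a 5-fold mean shift over a base NB mean of 0.5 with shape 2.0, and 30%
of measurements are zeroed post hoc.  The versioned ``standard_small`` fixture
(hex 20x20, 200 genes, 4 bands, de_frac 0.3, dropout 0.3, seed 7) is the
substrate for end-to-end checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SpatialDataset

__all__ = [
    "SimConfig", "make_lattice", "assign_domains", "simulate_expression",
    "make_dataset", "make_multislice", "standard_small",
]


@dataclass
class SimConfig:
    rows: int = 20
    cols: int = 20
    spacing: float = 1.0
    layout: str = "hex"           # hex | grid
    n_domains: int = 4
    domain_pattern: str = "bands"  # bands | blobs
    n_genes: int = 200
    de_frac: float = 0.3
    nb_mean_base: float = 0.5
    nb_mean_fold: float = 5.0
    nb_dispersion: float = 2.0    # NB shape; larger = closer to Poisson
    dropout_rate: float = 0.3
    n_slices: int = 1
    batch_log_fc_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.rows, self.cols, self.n_genes, self.n_domains,
               self.n_slices) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.layout not in ("hex", "grid"):
            raise ValueError("layout must be 'hex' or 'grid'")
        if self.domain_pattern not in ("bands", "blobs"):
            raise ValueError("domain_pattern must be 'bands' or 'blobs'")


def standard_small(**overrides) -> SimConfig:
    """The versioned small fixture: hex 20x20, 200 genes, 4 band domains,
    de_frac 0.3, dropout 0.3, seed 7."""
    cfg = SimConfig(rows=20, cols=20, layout="hex", n_domains=4,
                    domain_pattern="bands", n_genes=200, de_frac=0.3,
                    dropout_rate=0.3, seed=7)
    return replace(cfg, **overrides)


def make_lattice(cfg: SimConfig) -> np.ndarray:
    """Spot coordinates; N = rows * cols.

    Hex: odd rows offset by spacing/2 with vertical pitch spacing*sqrt(3)/2,
    so every interior spot has 6 equidistant nearest neighbors.  Grid: square
    lattice with 4 nearest neighbors at the spacing distance.
    """
    if cfg.rows < 2 or cfg.cols < 2:
        raise ValueError("rows and cols must be >= 2")
    r = np.repeat(np.arange(cfg.rows), cfg.cols)
    c = np.tile(np.arange(cfg.cols), cfg.rows)
    if cfg.layout == "hex":
        x = (c + 0.5 * (r % 2)) * cfg.spacing
        y = r * cfg.spacing * np.sqrt(3) / 2
    else:
        x = c * cfg.spacing
        y = r * cfg.spacing
    return np.column_stack([x, y]).astype(float)


def assign_domains(coords: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Domain labels in 1..n_domains; bands are contiguous horizontal strata,
    blobs are nearest-seed Voronoi regions (re-seeded until all nonempty)."""
    coords = np.asarray(coords)
    n = len(coords)
    if cfg.domain_pattern == "bands":
        if cfg.n_domains > cfg.rows:
            raise ValueError("bands need n_domains <= rows")
        ys = np.unique(coords[:, 1])
        row_of = np.searchsorted(ys, coords[:, 1])
        # split rows into n_domains contiguous, near-equal groups
        bounds = np.linspace(0, len(ys), cfg.n_domains + 1)
        return (np.searchsorted(bounds[1:-1], row_of, side="right") + 1)
    rng = np.random.default_rng(cfg.seed)
    for _ in range(10):
        seeds = coords[rng.choice(n, size=cfg.n_domains, replace=False)]
        d = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = d.argmin(axis=1) + 1
        if len(np.unique(labels)) == cfg.n_domains:
            return labels
    raise RuntimeError("could not draw nonempty Voronoi domains in 10 attempts")


def simulate_expression(labels: np.ndarray, cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Negative-binomial counts with domain-programmed folds plus dropout.

    Informative genes (a ``de_frac`` fraction, assigned round-robin to
    domains) have mean ``nb_mean_base * nb_mean_fold`` inside their domain
    and ``nb_mean_base`` elsewhere.  Returns (counts, truth table with each
    gene's domain and fold).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    n = len(labels)
    g = cfg.n_genes
    n_info = int(round(cfg.de_frac * g))
    gene_domain = np.zeros(g, dtype=int)  # 0 = uninformative
    domains = np.unique(labels)
    gene_domain[:n_info] = domains[np.arange(n_info) % len(domains)]

    mean = np.full((n, g), cfg.nb_mean_base)
    for gi in range(n_info):
        mean[labels == gene_domain[gi], gi] *= cfg.nb_mean_fold

    counts = _nb_sample(mean, cfg.nb_dispersion, rng).astype(float)
    if cfg.dropout_rate > 0:
        keep = rng.random((n, g)) >= cfg.dropout_rate
        counts *= keep
    truth = pd.DataFrame({
        "gene": [f"g{i}" for i in range(g)],
        "domain": gene_domain,
        "fold": np.where(gene_domain > 0, cfg.nb_mean_fold, 1.0),
    })
    return counts, truth


def _nb_sample(mean: np.ndarray, shape: float,
               rng: np.random.Generator) -> np.ndarray:
    """NB with given mean and shape (variance = mean + mean^2/shape)."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def make_dataset(cfg: SimConfig | None = None
                 ) -> tuple[SpatialDataset, pd.DataFrame]:
    """One slice: lattice + domains + counts; labels carried as ground truth."""
    cfg = cfg or SimConfig()
    coords = make_lattice(cfg)
    labels = assign_domains(coords, cfg)
    counts, truth = simulate_expression(labels, cfg)
    ds = SpatialDataset(
        expr=counts, coords=coords,
        spot_ids=[f"spot{i}" for i in range(len(coords))],
        gene_ids=[f"g{i}" for i in range(cfg.n_genes)],
        labels=labels,
    )
    return ds, truth


def make_multislice(cfg: SimConfig, n_slices: int | None = None,
                    batch_log_fc_sd: float | None = None
                    ) -> tuple[list[SpatialDataset], pd.DataFrame]:
    """Identical domain geometry per slice; counts drawn independently with
    per-slice per-gene multiplicative batch factors exp(N(0, sd)) on the NB
    mean.  Truth labels are identical across slices."""
    n_slices = n_slices if n_slices is not None else cfg.n_slices
    sd = batch_log_fc_sd if batch_log_fc_sd is not None else cfg.batch_log_fc_sd
    if n_slices < 2:
        raise ValueError("make_multislice needs n_slices >= 2")
    rng = np.random.default_rng(cfg.seed)
    coords = make_lattice(cfg)
    labels = assign_domains(coords, cfg)

    g = cfg.n_genes
    n_info = int(round(cfg.de_frac * g))
    gene_domain = np.zeros(g, dtype=int)
    domains = np.unique(labels)
    gene_domain[:n_info] = domains[np.arange(n_info) % len(domains)]
    base_mean = np.full((len(labels), g), cfg.nb_mean_base)
    for gi in range(n_info):
        base_mean[labels == gene_domain[gi], gi] *= cfg.nb_mean_fold

    slices = []
    for s in range(n_slices):
        factor = np.exp(rng.normal(0.0, sd, size=g)) if sd > 0 else np.ones(g)
        counts = _nb_sample(base_mean * factor[None, :],
                            cfg.nb_dispersion, rng).astype(float)
        if cfg.dropout_rate > 0:
            keep = rng.random(counts.shape) >= cfg.dropout_rate
            counts *= keep
        slices.append(SpatialDataset(
            expr=counts, coords=coords.copy(),
            spot_ids=[f"spot{i}" for i in range(len(coords))],
            gene_ids=[f"g{i}" for i in range(g)],
            labels=labels.copy(),
        ))
    truth = pd.DataFrame({
        "gene": [f"g{i}" for i in range(g)],
        "domain": gene_domain,
        "fold": np.where(gene_domain > 0, cfg.nb_mean_fold, 1.0),
    })
    return slices, truth
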