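"""Gene filtering, library-size normalization, log transform and HVG selection.

The pipeline order is: prevalence filter -> per-spot normalization to a
common target total -> log1p -> highly-variable-gene selection.  Mitochondrial
genes (symbols starting ``MT-``/``mt-``) and any user-supplied exclusion list
are dropped up front.  HVG ranking uses the Seurat-flavor mean-binned
normalized dispersion via scanpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .io import SpatialDataset

__all__ = [
    "PreprocessConfig", "filter_genes", "normalize_log", "select_hvg",
    "drop_excluded_genes", "preprocess",
]


@dataclass
class PreprocessConfig:
    min_cells: int = 3
    n_hvg: int = 3000
    normalize_target: Union[float, str] = "median"
    log_transform: bool = True
    skip_hvg: bool = False  # denoising runs keep all genes
    exclude_genes: list = field(default_factory=list)
    exclude_prefixes: tuple = ("MT-", "mt-")

    def __post_init__(self):
        if not self.skip_hvg and self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1 when HVG selection is on")
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")


def drop_excluded_genes(dataset: SpatialDataset,
                        exclude: list = (),
                        prefixes: tuple = ("MT-", "mt-")) -> SpatialDataset:
    """Remove explicitly excluded genes and prefix-matched (e.g. mito) genes."""
    excl = set(exclude)
    keep = [i for i, g in enumerate(dataset.gene_ids)
            if g not in excl and not any(g.startswith(p) for p in prefixes)]
    if len(keep) == dataset.n_genes:
        return dataset
    if not keep:
        raise ValueError("exclusion rules removed every gene")
    return dataset.with_expr(dataset.expr[:, keep],
                             [dataset.gene_ids[i] for i in keep])


def filter_genes(dataset: SpatialDataset, min_cells: int) -> SpatialDataset:
    """Keep genes detected (nonzero) in at least ``min_cells`` spots."""
    if min_cells == 0:
        return dataset
    prevalence = (dataset.expr > 0).sum(axis=0)
    keep = np.flatnonzero(prevalence >= min_cells)
    if keep.size == 0:
        hist = np.bincount(prevalence.astype(int))
        raise ValueError(
            f"no gene is detected in >= {min_cells} spots; "
            f"prevalence histogram (count of genes per #spots detected): {hist.tolist()}"
        )
    return dataset.with_expr(dataset.expr[:, keep],
                             [dataset.gene_ids[i] for i in keep])


def normalize_log(dataset: SpatialDataset,
                  target: Union[float, str] = "median",
                  log_transform: bool = True) -> SpatialDataset:
    """Scale each spot to a common total, then apply natural log1p.

    ``target="median"`` uses the median total over spots with nonzero totals.
    Spots with zero total stay all-zero (with a warning).
    """
    expr = np.asarray(dataset.expr, dtype=float)
    totals = expr.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("every spot has zero total expression")
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} spot(s) with zero total left as zeros")
    tgt = float(np.median(totals[nonzero])) if target == "median" else float(target)
    if tgt <= 0:
        raise ValueError("normalization target must be positive")
    scale = np.ones_like(totals)
    scale[nonzero] = tgt / totals[nonzero]
    out = expr * scale[:, None]
    if log_transform:
        out = np.log1p(out)
    return dataset.with_expr(out)


def select_hvg(dataset: SpatialDataset, n_hvg: int) -> SpatialDataset:
    """Keep the top ``n_hvg`` genes by binned normalized dispersion.

    Expects normalized/log data.  Identity when G <= n_hvg.  Deterministic.
    """
    if dataset.n_genes <= n_hvg:
        return dataset
    import scanpy as sc
    import anndata as ad
    adata = ad.AnnData(X=dataset.expr.astype(np.float64))
    adata.var_names = dataset.gene_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_hvg)
    keep = np.flatnonzero(adata.var["highly_variable"].to_numpy())
    return dataset.with_expr(dataset.expr[:, keep],
                             [dataset.gene_ids[i] for i in keep])


def preprocess(dataset: SpatialDataset,
               config: PreprocessConfig | None = None) -> SpatialDataset:
    """Full pipeline: exclusions -> prevalence filter -> normalize+log -> HVG."""
    cfg = config or PreprocessConfig()
    ds = drop_excluded_genes(dataset, cfg.exclude_genes, cfg.exclude_prefixes)
    ds = filter_genes(ds, cfg.min_cells)
    ds = normalize_log(ds, cfg.normalize_target, cfg.log_transform)
    if not cfg.skip_hvg:
        ds = select_hvg(ds, cfg.n_hvg)
    return ds
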