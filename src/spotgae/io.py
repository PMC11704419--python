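"""Reading and writing spatial expression bundles.

A bundle is a Matrix Market expression matrix (genes x spots on disk, the
common single-cell dialect; transposed to spots x genes in memory) plus TSV
sidecars for spot coordinates, gene identifiers and optional labels, tied
together by a JSON manifest with SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["SpatialDataset", "read_bundle", "read_h5ad", "write_bundle",
           "stack_slices"]


@dataclass
class SpatialDataset:
    """Spot-level expression with planar coordinates.

    ``expr`` is N x G (spots x genes), nonnegative.  ``slice_idx`` carries
    the discrete vertical position for multi-slice stacks (contiguous
    integers starting at 1); single-slice data uses all ones.  The vertical
    axis is never a metric z coordinate — cross-slice adjacency is a
    relation between consecutive slice indices.
    """

    expr: np.ndarray
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    slice_idx: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.expr = np.asarray(self.expr)
        if sp.issparse(self.expr):  # pragma: no cover - defensive
            self.expr = self.expr.toarray()
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.expr.shape
        if n < 1 or g < 1:
            raise ValueError(f"need N >= 1 and G >= 1, got N={n}, G={g}")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match N={n} spots"
            )
        if not np.all(np.isfinite(self.expr)):
            raise ValueError("expression matrix contains NaN/Inf")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain NaN/Inf")
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} matrix rows")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_id")
        if len(self.gene_ids) != g or len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique and match matrix columns")
        if self.slice_idx is None:
            self.slice_idx = np.ones(n, dtype=int)
        self.slice_idx = np.asarray(self.slice_idx, dtype=int)
        if self.slice_idx.shape != (n,):
            raise ValueError("slice_idx length mismatch")
        uniq = np.unique(self.slice_idx)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("slice_idx values must be contiguous from 1")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length mismatch")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    @property
    def n_slices(self) -> int:
        return int(self.slice_idx.max())

    def with_expr(self, expr, gene_ids=None) -> "SpatialDataset":
        return replace(
            self, expr=expr,
            gene_ids=self.gene_ids if gene_ids is None else list(gene_ids),
        )

    def subset_slices(self, which: list[int]) -> list["SpatialDataset"]:
        """Split into per-slice datasets (slice_idx reset to 1)."""
        out = []
        for s in which:
            m = self.slice_idx == s
            out.append(SpatialDataset(
                expr=self.expr[m],
                coords=self.coords[m],
                spot_ids=[sid for sid, keep in zip(self.spot_ids, m) if keep],
                gene_ids=list(self.gene_ids),
                slice_idx=np.ones(int(m.sum()), dtype=int),
                labels=None if self.labels is None else self.labels[m],
            ))
        return out


def stack_slices(slices: list["SpatialDataset"]) -> "SpatialDataset":
    """Concatenate per-slice datasets into one multi-slice dataset.

    Rows are grouped by slice in the given (stacking) order; slice_idx is
    assigned 1..S.  Gene sets must agree.
    """
    if not slices:
        raise ValueError("no slices given")
    genes = slices[0].gene_ids
    for s in slices[1:]:
        if s.gene_ids != genes:
            raise ValueError("slices have differing gene sets")
    spot_ids = []
    for k, s in enumerate(slices, start=1):
        spot_ids += [f"s{k}:{sid}" for sid in s.spot_ids]
    labels = None
    if all(s.labels is not None for s in slices):
        labels = np.concatenate([s.labels for s in slices])
    return SpatialDataset(
        expr=np.vstack([s.expr for s in slices]),
        coords=np.vstack([s.coords for s in slices]),
        spot_ids=spot_ids,
        gene_ids=list(genes),
        slice_idx=np.concatenate([
            np.full(s.n_spots, k, dtype=int)
            for k, s in enumerate(slices, start=1)
        ]),
        labels=labels,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_bundle(matrix_path, coords_path, genes_path,
                labels_path=None) -> SpatialDataset:
    """Load a bundle from disk.

    The matrix may be Matrix Market (genes x spots, transposed at load) or a
    dense TSV (spots x genes, no header).  The coordinate TSV must have
    columns spot_id, x, y and optionally slice.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(str(matrix_path))
        expr = np.asarray(sp.csr_matrix(mat).todense()).T  # genes x spots on disk
    else:
        expr = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    coords_df = pd.read_csv(coords_path, sep="\t")
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ValueError(f"coords TSV needs columns {sorted(required)}")
    if expr.shape[0] != len(coords_df):
        raise ValueError(
            f"matrix has {expr.shape[0]} spots but coords file has "
            f"{len(coords_df)} rows"
        )
    gene_ids = [ln.strip() for ln in Path(genes_path).read_text().splitlines()
                if ln.strip()]
    spot_ids = coords_df["spot_id"].astype(str).tolist()
    slice_idx = (coords_df["slice"].to_numpy(dtype=int)
                 if "slice" in coords_df.columns else None)
    labels = None
    if labels_path is not None:
        lab_df = pd.read_csv(labels_path, sep="\t")
        lab_map = dict(zip(lab_df["spot_id"].astype(str), lab_df["label"]))
        labels = np.array([lab_map[s] for s in spot_ids])
    return SpatialDataset(expr=expr, coords=coords_df[["x", "y"]].to_numpy(),
                          spot_ids=spot_ids, gene_ids=gene_ids,
                          slice_idx=slice_idx, labels=labels)


def read_h5ad(path, spatial_key: str = "spatial", slice_key: str = "slice",
              label_key: str = "label") -> SpatialDataset:
    """Load an AnnData container: X (spots x genes), obsm[spatial_key] for
    coordinates, optional obs columns for slice index and labels."""
    import anndata as ad
    adata = ad.read_h5ad(path)
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    if spatial_key not in adata.obsm:
        raise ValueError(f"obsm['{spatial_key}'] missing from {path}")
    coords = np.asarray(adata.obsm[spatial_key])[:, :2]
    slice_idx = (adata.obs[slice_key].to_numpy(dtype=int)
                 if slice_key in adata.obs.columns else None)
    labels = (adata.obs[label_key].to_numpy()
              if label_key in adata.obs.columns else None)
    return SpatialDataset(expr=np.asarray(X, dtype=float), coords=coords,
                          spot_ids=adata.obs_names.tolist(),
                          gene_ids=adata.var_names.tolist(),
                          slice_idx=slice_idx, labels=labels)


def write_bundle(dataset: SpatialDataset, out_dir) -> dict:
    """Write MTX + TSV sidecars + manifest; returns the manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mtx_path = out_dir / "matrix.mtx"
    expr = dataset.expr
    integral = np.all(expr == np.round(expr))
    disk = sp.coo_matrix(expr.T)  # genes x spots on disk
    if integral:
        disk = disk.astype(np.int64)
        scipy.io.mmwrite(str(mtx_path), disk, field="integer")
    else:
        scipy.io.mmwrite(str(mtx_path), disk, precision=17)

    coords_df = pd.DataFrame({
        "spot_id": dataset.spot_ids,
        "x": dataset.coords[:, 0],
        "y": dataset.coords[:, 1],
        "slice": dataset.slice_idx,
    })
    coords_path = out_dir / "coords.tsv"
    coords_df.to_csv(coords_path, sep="\t", index=False, float_format="%.17g")

    genes_path = out_dir / "genes.tsv"
    genes_path.write_text("\n".join(dataset.gene_ids) + "\n")

    files = [mtx_path, coords_path, genes_path]
    if dataset.labels is not None:
        labels_path = out_dir / "labels.tsv"
        pd.DataFrame({"spot_id": dataset.spot_ids,
                      "label": dataset.labels}).to_csv(
            labels_path, sep="\t", index=False)
        files.append(labels_path)

    manifest = {
        "orientation": "matrix.mtx is genes x spots; in-memory is spots x genes",
        "n_spots": dataset.n_spots,
        "n_genes": dataset.n_genes,
        "files": {f.name: _sha256(f) for f in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_embeddings(spot_ids, H, path):
    df = pd.DataFrame(H, columns=[f"dim{i}" for i in range(H.shape[1])])
    df.insert(0, "spot_id", list(spot_ids))
    df.to_csv(path, sep="\t", index=False)


def write_clusters(spot_ids, labels, path):
    pd.DataFrame({"spot_id": list(spot_ids), "cluster": labels}).to_csv(
        path, sep="\t", index=False)
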