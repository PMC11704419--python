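# spotgae

Self-supervised spot embeddings for spatial transcriptomics via a
dual-remask dynamic graph-attention autoencoder.

Spatial transcriptomics measures expression at spots with known positions,
but the readout is noisy and riddled with technical zeros (dropout), which
makes spatial-domain clustering, microenvironment analysis and multi-slice
integration fragile.  `spotgae` addresses this for analysts working with
Visium-style lattices or single-cell-resolution platforms: it learns a
low-dimensional embedding per spot that pools information over the spatial
neighbor graph while being trained, deliberately, on heavily corrupted
inputs — so the representation cannot rely on any single spot's (possibly
dropped-out) measurements.

## Method in brief

Given a graph G = (V, A, X) of N spots with adjacency A and expression
X ∈ ℝ^{N×d}, each training epoch:

1. **MASK** — 50% of spots have their features replaced by a learnable
   token x₍M₎ (5% of them instead receive another random spot's features);
   the rest are **KEEP**t unchanged.
2. **Encode** — dynamic graph attention: eᵢⱼ = vᵀ σ(W₀hᵢ + W₁hⱼ),
   attᵢⱼ = softmax over the neighborhood Nᵢ (which includes i), and
   hᵢ^(k) = ELU(Σⱼ attᵢⱼ W₀ hⱼ); the final layer aggregates without
   attention.  Default widths d → 512 → 30.
3. **REMASK** — the latent H is corrupted twice more, independently, with a
   second token h₍M₎ (50% of rows each).
4. **Decode twice** — one decoder whose weights are the transposed encoder
   weights (Ŵ₀ᵀ = W₀) and whose attention is the encoder's, applied to both
   remasked latents: Z⁰, Z¹.
5. **Loss** — scaled cosine error
   L = 1/|Ṽ| Σ_{i∈Ṽ} (1−cos(xᵢ, zᵢ⁰))^γ + 1/(N−|Ṽ|) Σ_{i∉Ṽ} (1−cos(xᵢ, zᵢ¹))^γ
   + WD·Σ‖W‖²,  optimized by Adam (lr 0.001, γ = 2 by default).

One view predicts the masked spots (noise correction), the other
reconstructs the kept spots (detail recovery).  At inference the uncorrupted
input is encoded once: H feeds clustering/visualization, a single tied
decode gives denoised expression, and the attention coefficients are
exported as spatially positioned edge weights for microenvironment
inspection.  Multi-slice stacks are trained jointly on a cross-slice
neighbor graph (pooled KNN for two slices; adjacent-slice capture, at most
7 spots per neighboring slice, for three or more), which mixes slice-level
batch effects in the latent space without any explicit correction step.

The model and training loop are pure NumPy on a small reverse-mode autodiff
core shipped with the package; results are exactly reproducible on CPU for
a fixed seed.

## Worked example

```python
import numpy as np
import spotgae as sg

# synthetic Visium-like slice: hex 20x20 lattice, 4 banded domains,
# 200 genes (30% domain-informative, 5-fold), 30% dropout
ds, truth = sg.make_dataset(sg.standard_small())
pp = sg.preprocess(ds, sg.PreprocessConfig())        # filter, normalize, log1p
g = sg.build_sng_knn(pp.coords, 6)                   # 6-neighbor lattice graph
params, log = sg.fit(pp, g, sg.TrainingConfig(epochs=300, seed=0))
H = sg.get_latent(pp, g, params)                     # 400 x 30
res = sg.cluster_latent(H, 4, seed=0)
print(f"loss: {log[0].total:.3f} -> {log[-1].total:.3f}")
print(f"ARI vs generating domains: {sg.ari(res.labels, ds.labels):.3f}")
```

Output:

```
loss: 1.707 -> 0.400
ARI vs generating domains: 1.000
```

The loss falls as the dual views learn to reconstruct masked and kept spots,
and clustering the 30-dimensional latent recovers the four planted spatial
domains exactly; clustering the raw log-normalized expression instead is
noticeably less stable under dropout and batch shifts.

The same pipeline is available from the shell:

```bash
spotgae simulate --outdir bundle --seed 7
spotgae preprocess --indir bundle --outdir pp
spotgae train --indir pp --outdir run --epochs 300 --seed 0
spotgae cluster --embeddings run/embeddings.tsv -k 4 --out run/clusters.tsv
spotgae run --config config.toml     # all-in-one with resume-on-rerun
```

## Layout

- `src/spotgae/io.py` — MTX/TSV bundle reading and writing, manifests
- `src/spotgae/preprocess.py` — gene filtering, normalization, HVG selection
- `src/spotgae/graph.py` — radius / covering-KNN / two-slice / stacked-slice graphs
- `src/spotgae/masking.py` — MASK/KEEP/REMASK plans and application
- `src/spotgae/autodiff.py` — minimal reverse-mode autodiff on NumPy
- `src/spotgae/model.py` — dynamic graph attention encoder + tied decoder
- `src/spotgae/train.py` — SCE losses, Adam loop, inference passes
- `src/spotgae/downstream.py` — GMM clustering, ARI/NMI/FMS, iLISI, attention export
- `src/spotgae/simulate.py` — synthetic lattice/domain/count generator
- `src/spotgae/cli.py` — `spotgae` command-line interface

See `docs/methods.md` for the full model description, parameter meanings,
and what the synthetic fixtures do and do not demonstrate.
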