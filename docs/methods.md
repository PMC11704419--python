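# Methods

## Model

`spotgae` learns spot embeddings for spatial transcriptomics by
reconstruction under heavy, repeated corruption on a spatial neighbor graph.
The data are a graph G = (V, A, X): spots V with binary symmetric adjacency
A built from their planar coordinates, and an N x G expression matrix X
(normalized, log1p-transformed).

**Spatial neighbor graph (SNG).** Two single-slice builders: a fixed
Euclidean radius (edge iff 0 < d(i, j) < r), suited to sub-cellular
platforms; and covering-radius KNN, suited to lattice chips — each spot links
to every spot within the distance of its k-th nearest neighbor, so distance
ties are included deterministically and an interior spot of a hexagonal
lattice at k = 6 gets exactly its 6-ring.  Two co-registered slices are
pooled into one KNN point set.  Stacks of three or more slices link each
spot within its slice (k = 6) and to at most 7 spots of each immediately
adjacent slice (the minimal in-plane radius covering 7 points of that slice;
on a perfect stack this is the directly-facing spot plus its 6-ring).
Non-adjacent slices are never linked, so an outer-slice interior spot has at
most 6 + 7 = 13 neighbors and a middle-slice one at most 6 + 7 + 7 = 20.
The stored graph has no self-loops; the model's aggregation neighborhood
N_i always includes i itself.

**MASK / KEEP / REMASK.** Before every epoch, floor(0.5 N) spots are masked:
5% of the masked spots receive the raw features of a spot drawn uniformly
from all spots, the rest are replaced by a learnable input-space token.
Kept spots are untouched.  After encoding, the latent matrix is corrupted
twice more, independently: each remask draw replaces floor(0.5 N) rows
(drawn uniformly, regardless of the input mask) with a second learnable
token.  Counts use floor, under- rather than over-masking.  For
microenvironment-heterogeneity runs the replacement rate is 0%.

**Dynamic graph attention (DGAT).** Attention layers score neighbor j of
query i as e_ij = v' sigmoid(W0 h_i + W1 h_j) — the nonlinearity is applied
*before* the scoring projection, so the neighbor ranking can change with the
query node (unlike static single-projection attention).  Softmax over N_i
(max-stabilized) gives att_ij; the hidden state is
ELU(sum_j att_ij W0 h_j).  The last encoder layer drops the attention
weighting and sums W0 h_j over N_i unchanged (no degree normalization — an
optional mean-aggregation switch exists but defaults off).  No bias terms;
ELU alpha = 1.  Default widths are input -> 512 -> 30, giving a
30-dimensional latent and second-order neighborhood context.

**Tied decoder, dual view.** The decoder runs the stack in reverse using the
*transposed* encoder weights and reuses the encoder's attention coefficients
verbatim; its last step is again unweighted.  There are no decoder-side
parameters at all — the trainable state is the encoder weights, the
attention vectors, and the two tokens.  Both remasked latents pass through
this one decoder, giving reconstructions Z0 and Z1.

**Loss.** Scaled cosine error per view:
L_sce0 = mean over masked spots of (1 - cos(x_i, z0_i))^gamma and
L_sce1 = the same over kept spots against Z1, plus an explicit L2 penalty
WD * sum ||W||^2 over every W0 and W1.  gamma in [1, 3] (default 2, the
midpoint; larger values suit complex tissue) controls how steeply
easy examples are down-weighted.  Adam (lr 0.001) optimizes the total; the
optimizer's internal weight decay is zero because the penalty is already in
the loss — keeping both would penalize the weights twice.

**Inference.** Embeddings and denoised expression come from the uncorrupted
input: one encoder pass for H, one tied decode of H for Z.  Masking at
inference would make embeddings stochastic and unusable downstream, so no
corruption is applied.  All inference is deterministic.

## Numerical core

The model, its gradients and the Adam loop are implemented in NumPy (double
precision) on top of a small in-repo reverse-mode autodiff engine
(`spotgae.autodiff`) providing dense matmul, gather/scatter-add over edge
lists, segment softmax, ELU/sigmoid, and the cosine loss.  Gradients are
verified against central differences in the test suite, and the sparse
forward pass is verified to 1e-10 against a dense loop-level evaluation of
the layer equations on small graphs.  With a fixed seed, training is exactly
reproducible on CPU.  One RNG stream drives initialization and the per-epoch
mask / remask-view-0 / remask-view-1 draws in a fixed order.

## Downstream analysis

Latent embeddings are clustered with a Gaussian mixture using a shared
(tied) covariance across components, K fixed to the annotation count.
Initialization uses full k-means (itself k-means++ seeded): bare k-means++
point seeding can hand EM a degenerate start (one dominant component) on
the anisotropic latents this model produces, while a k-means start is
reliably near the basin the mixture refines.  Agreement with ground truth is
scored by ARI, NMI and FMS; unsupervised dispersion by Calinski–Harabasz and
Davies–Bouldin.  Batch mixing is scored by iLISI: per spot, a Gaussian
kernel over its 3 x perplexity nearest embedding neighbors is calibrated to
perplexity 30 by bisection, and the index is the inverse Simpson's index of
the weighted batch proportions (1 = unmixed, B = perfectly mixed).
Attention coefficients of trained models are exported as directed edge
tables positioned by spot coordinates for microenvironment-heterogeneity
inspection.

## Preprocessing

Order: exclusion rules -> prevalence filter -> normalization -> log1p -> HVG
selection.  Mitochondrial genes (``MT-``/``mt-`` prefixes) and any explicit
exclusion list are dropped first; genes detected in fewer than 3 spots are
removed; each spot is scaled to the median spot total (the conventional
normalize-then-log order); the top 3000 genes by Seurat-flavor binned
normalized dispersion are kept (identity when fewer genes exist; skipped
entirely for denoising runs, where reconstructions of all genes are wanted).

## Synthetic data

The generator emulates what the method needs from real data and nothing
more: lattice geometry (hex or grid), spatially coherent domains
(contiguous horizontal bands, cortical-layer-like, or Voronoi blobs),
overdispersed counts, technical zeros, and slice-level batch shifts.
Counts are negative binomial with mean 0.5 (shape 2.0); each informative
gene (30% of genes, assigned round-robin to domains) has a 5-fold mean
shift inside its domain — marker-gene scale.  Independent Bernoulli(0.3)
zeroing is applied afterwards, mimicking dropout.  Multi-slice stacks reuse
one domain geometry and draw counts independently per slice with per-slice
per-gene multiplicative factors exp(N(0, sd)) on the NB mean (sd 0.5 for
batch-mixing experiments).

What this does **not** emulate: irregular tissue morphology, within-domain
expression gradients, spatially correlated dropout, cell-type mixtures
within spots, or alignment error between slices.  Passing tests on these
fixtures demonstrates that the machinery recovers planted spatial structure
under overdispersion, dropout and batch shifts — not performance on any
real tissue.

The versioned fixture ``standard_small`` (hex 20 x 20 = 400 spots, 200
genes, 4 band domains, de_frac 0.3, dropout 0.3, seed 7) is the substrate
for the end-to-end checks; its size keeps a full 300-epoch training run
around 1–2 minutes on one CPU while leaving the domain-recovery problem
non-trivial (raw-expression clustering does not reach the graph model's
accuracy on the batch-shifted variants).

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| k (SNG) | 6 | lattice neighbor count; covering radius includes ties |
| cross_cap | 7 | max cross-slice captures per spot and adjacent slice |
| mask_ratio | 0.5 | fraction of spots masked per epoch |
| replace_ratio | 0.05 | fraction of masked spots feature-swapped (0 for heterogeneity runs) |
| remask_ratio | 0.5 | fraction of latents re-corrupted per decoding view |
| dims | (512, 30) | encoder widths; latent dimension 30 |
| gamma | 2.0 | SCE exponent, sensible range [1, 3] |
| lr / WD | 0.001 / 0.001 | Adam step size; explicit L2 coefficient |
| epochs | 500 | no early stopping; 300 suffices on the standard fixture |

## Degenerate inputs and edge cases

Isolated nodes attend only to themselves (att_ii = 1).  Zero-norm rows in
the cosine loss contribute cosine 0 through an epsilon guard, with a
warning.  Zero-total spots pass through normalization unchanged (warning).
mask_ratio = 0 leaves the masked-view loss undefined and is rejected unless
the kept-view-only objective is requested explicitly.  KNN ties are resolved
by inclusion (covering radius), never by input order, so every builder is
order-independent and all adjacencies are exactly symmetric.

## Known limitations

Full-graph batch training only (no mini-batching), so memory grows with
N x max(width); practical to a few tens of thousands of spots on CPU.
Single-head attention.  Slice co-registration is assumed, never computed.
The clustering step requires K; no model-selection over K is attempted.
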