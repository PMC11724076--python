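# Methods

## The model

`mrepinsight` classifies tabular samples by converting them into images and
pooling a convolutional classifier's opinions across several such
conversions.  Let `M ∈ R^{d×n}` be the training matrix (d features, n
samples, entries `g_ij`) with labels `ω_j ∈ {1..c}`.  One *representation*
is a recipe `λ_r = (technique, metric, filter)`:

1. **Feature embedding.** The *transpose* of `M` is embedded in the plane,
   so each of the d features receives a 2-D point `L(g_i | λ_r)`.
   Techniques: t-SNE (euclidean, cosine, chebychev, hamming or mahalanobis
   distances), UMAP, PCA, kernel PCA.
2. **Alignment.** The minimum-area rectangle enclosing the d points is found
   by rotating calipers over the convex hull (the optimal rectangle has a
   side collinear with a hull edge) and the cloud is rotated so the
   rectangle is axis-parallel.
3. **Discretization.** The rotated rectangle is mapped onto a `p×q` grid of
   half-open cells, preserving aspect ratio (the short axis is letterboxed
   and centered); feature i gets the integer pixel `[a_i, b_i]`.
4. **Rendering.** A normalized sample `x ∈ [0,1]^d` becomes a `p×q` image
   with `x_i` written at `[a_i, b_i]`; features sharing a pixel are
   aggregated (mean by default).  An optional enhancement filter (Gaussian
   blur or a Gabor bank) is applied to the rendered image.

With m representations, the n training samples yield `n·m` labeled images on
which a single CNN `Ψ` is trained.  A test sample `x_t` is rendered through
all m frozen pixel maps (no re-fitting at test time), giving images
`R_1..R_m`; the network produces probability rows `ρ^(r) = ψ(W, R_r)`, their
unweighted mean `ρ_avg = (1/m) Σ_r ρ^(r)` is taken, and the predicted class
is `argmax ρ_avg` (lowest index on an exact tie).  With m = 1 the procedure
is exactly the single-representation predecessor.

## Parameters that matter

| Parameter | Default | Notes |
|---|---|---|
| grid `p×q` | 50×50 (`compute_pixel_map`); 24×24 in the benchmark runner | pixels; small grids force feature collisions, large grids dilute the receptive field |
| t-SNE perplexity | `min(30, (d−1)/3)` | clamped below the point count for small d; exact-gradient solver below 2000 features |
| UMAP `n_neighbors` | `min(15, d−1)` | |
| blur `sigma` | 1.0 | pixels; output rescaled so the peak matches the input peak |
| Gabor bank | 4 orientations × frequencies (0.1, 0.25) | maximum response magnitude, rescaled to [0,1] |
| collision | `mean` | value-preserving under the [0,1] normalization; `max` available |
| learning rate / weight decay / momentum | 0.01 / 1e-4 / 0.9 | SGD; see backbone note below |
| epochs / batch | 15 / 128 | checkpoint with the lowest validation loss is restored |

**Normalization.**  Values are rescaled per feature to [0,1] with training
statistics; test-time values are clipped into [0,1] and constant features
map to 0.  Two variants are shipped (`minmax` and `l2_minmax`, which first
divides each feature by its training L2 norm); because min-max is invariant
to positive rescaling, the variants produce identical output on
non-degenerate features — both exist because both readings of the
"norm-2" rescaling circulate in this method family.

**Hamming distances on continuous features.**  Raw hamming distance on real
values saturates (almost all coordinates differ), so each feature vector is
binarized at its own median before computing hamming distances; the t-SNE
then runs on the precomputed distance matrix.

**Mahalanobis distances.**  d feature points in an n-dimensional ambient
space can never span the covariance, so a ridge `ε = 1e-3` is always added;
the Woodbury identity reduces the computation to the d×d Gram matrix, so
the cost does not grow with n².

**The three-representation recipe** used on the two-Gaussian benchmark is
t-SNE(hamming), t-SNE(euclidean) + Gaussian blur, and UMAP.  The recipe
names an enhancement ("blurring") alongside two manifold techniques; we
attach the blur to the euclidean t-SNE because blurring is defined as an
enhancement of a manifold mapping and euclidean t-SNE is the lineage's
default manifold.

## The backbone

The default classifier is a compact CNN written directly on numpy: three
conv(3×3)–ReLU–maxpool blocks (8, 16, 32 channels), a 64-unit hidden dense
layer and a softmax head (~25k parameters at 24×24 input).  Convolutions
are im2col views driven through BLAS tensor products; training is SGD with
momentum 0.9 and L2 weight decay 1e-4, fully deterministic given the seed.
The step size defaults to 0.01: the widely printed 0.001/0.0001/0.9
combination belongs to fine-tuning large pretrained backbones, which is too
small a step for a from-scratch compact network.  Named large backbones
(`resnet50`, `efficientnet_b6`) are accepted in `TrainConfig` as optional
plug-ins but require an external deep-learning framework with pretrained
weights and raise an informative error otherwise.

The epoch with the lowest validation loss is kept (checkpoint-best); with
no validation set the last epoch's weights are used and a warning is
emitted.

## Synthetic data

`ringnorm` draws class 1 from N(0, 4I) and class 2 from N((2/√d)·1, I) with
d = 20 and a 50/50 class prior (first class receives ⌈fraction·n⌉ samples,
the remainder goes to the last).  Its Bayes-optimal boundary is a quadric
(approximately a ring), with a Bayes error around 1.3% — easy for tree
ensembles and boosted trees, structurally impossible for a linear model.

`madelon_style` emulates the classic nonlinear feature-selection benchmark:
per-class clusters on hypercube vertices in a small informative subspace,
exactly-redundant linear combinations, pure-noise irrelevant features, 1%
label flips, and a recorded feature permutation so tests can invert it.
It does not reproduce the original benchmark's exact files.

`gaussian_blobs` is a deterministic separable fixture for fast tests.

What the generators do *not* emulate: real transcriptomic structure
(sparsity, overdispersion, batch effects, correlated gene modules).  Tests
passing on these generators demonstrate the pipeline's mechanics and its
behavior under known statistical structure, not performance on real
single-cell or clinical data.

## Numerical choices

- Rectangle rotation is reported in [0, 90) (a rectangle is invariant under
  90° rotations); among equal-area candidates the smallest non-negative
  angle wins.  Collinear point sets are aligned with their principal axis so
  the degenerate extent is the height (the grid collapses to one row);
  a single point maps to pixel (0, 0).
- Grid cells are half-open `[k, k+1)` with a top-left origin (row = a,
  col = b); the maximum rotated y lands in row 0.  Values on the far edge
  are clipped into the last cell.
- Argmax ties break to the lowest class index, deterministically.
- t-SNE uses PCA initialization for built-in metrics and random
  initialization (seeded) for precomputed distances; with fewer than three
  features, t-SNE/UMAP fall back to PCA with a warning.
- Baseline grids (validation-tuned): random forest 200 trees ×
  max_features {sqrt, all}; logistic regression C ∈ {0.01, 0.1, 1, 10} after
  standardization; level-wise boosting depth {3, 6} at 300 rounds; leaf-wise
  boosting leaves {31, 63} at 300 rounds, learning rate 0.1.  The winning
  grid point's fitted model (trained on the training partition only) is
  scored once on the test partition.

## Problem sizes used by the shipped tests and benchmark

The benchmark runner uses the full generated protocol (7400 samples, split
5920/740/740) for the tabular baselines over five seeds, and the image
pipeline at grid 24×24 with 15 epochs over two seeds — sizes chosen so the
whole comparison runs on a single desktop CPU core.  Unit tests use far
smaller fixtures (hundreds of samples, 8–16 pixel grids, a few epochs).

## Known limitations

- On low-dimensional, noise-free generated problems the compact CNN comes
  close to the Bayes accuracy (~98.7% on ringnorm), *exceeding* the
  reference accuracies reported for large transfer-learned backbones on the
  same distribution (96.4/96.5%).  A two-sided comparison against those
  reference values can therefore fail from above; this is a property of the
  backbone/benchmark pairing, not a defect of the transform.
- The assignment-distribution enhancement referenced in this method family
  is not implemented; requesting it raises `NotImplementedError`.
- Sparse input formats, batch correction and class-aware mapping variants
  are out of scope; augmentation by rotation/reflection of rendered images
  is deliberately absent (it breaks the frozen feature-pixel correspondence
  the transform relies on).
- Weighted ensemble voting is deliberately not offered: the averaging step
  is defined unweighted, and m is typically too small to fit weights
  without leaking validation information.
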