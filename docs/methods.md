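# Methods

## Problem setting

`alseg` studies pool-based active learning (AL) for two-class pixel-wise
segmentation: a femoral head and an acetabulum in a grayscale radiograph,
annotated as a three-channel binary mask (background, femur, acetabulum).
The two foreground channels may overlap — the femoral head sits inside
the acetabular cup — which is why masks are multi-label rather than a
single categorical map, and why the segmenter emits two independent
sigmoid channels with background implicit. The background channel is
defined as the complement of the union of the foreground channels, so a
mask is constructible from foreground annotations alone.

An experiment starts from a corpus split into a test set (15%), a
validation set (15%), an initial labeled set L₀ (3%) and an unlabeled
pool U₀ (the remainder). Fractions are parameters; partition sizes are
round-half-up with the remainder flowing to the pool. Test and validation
ids never enter the pool. At each iteration t an acquisition query
selects min(n, |U_t|) images, their held ground-truth masks are revealed
(simulated annotation; a hook point for a real oracle), the model is
retrained **from scratch** on L_t, and test dice is recorded. The loop
runs until U = ∅, i.e. ⌈|U₀|/n⌉ iterations; the whole cycle is repeated
(default 10 repeats, 3 in the desk-scale benchmark) with derived seeds
and the per-iteration curves averaged.

## Acquisition queries

*Cluster-based (diversity).* Images are flattened to pixel vectors
(optionally thumbnailed first), min-max normalized per feature — constant
features map to 0 with a warning — and reduced by PCA keeping the
**minimal** number of components whose cumulative explained-variance
ratio reaches 0.99. K-Means++ builds n clusters in the reduced pool and
each centroid claims its nearest pool element. When two centroids share a
nearest element, assignment is greedy by ascending centroid–element
distance with each element used once, guaranteeing n distinct selections.

*Representative.* R(x) = d(x, μ_L) − d(x, μ_U) with Euclidean d and
centroids taken as arithmetic means: a single K-Means cluster converges
to the mean, so no iterative fit is run. The PCA basis for this query is
fit on the concatenation U ∪ L — both sets must live in one space for
the two distances to be comparable. High R marks images typical of the
pool yet far from the training data.

*Class-wise entropy over Monte Carlo Dropout (uncertainty).* k = 30
forward passes with dropout active approximate the predictive
distribution; their elementwise mean P̄ is scored per image by averaging
−p log₂ p over pixels within each foreground channel and then across the
two channels. The per-pixel term is implemented literally as −p log₂ p
(maximized at p = 1/e); a `binary` variant supplying the full binary
entropy −p log₂ p − (1−p) log₂ (1−p) is available, since the literal
form can be read as shorthand for it. 0·log₂ 0 := 0 by continuity; only
the binary variant needs probability clipping (1e-7) for its logs.

*Borda fusion.* R and entropy scores are each converted to Borda points
(best of m gets m−1 down to 0; exact ties share the mean of their point
block, via average ranks) and summed. Points-summed-and-maximized was
chosen over competition-ranks-summed-and-minimized; the two differ only
under ties, and the points convention composes cleanly with average-rank
tie handling. All orderings break remaining ties by stable (pool input)
id order, so every query is deterministic given its seed.

## Metrics and training objective

Evaluation dice binarizes sigmoid outputs at 0.5 and scores each
foreground class as 2|G∩P|/(|G|+|P|), macro-averaged; a class empty in
both prediction and truth scores 1. The training objective is soft dice
(un-thresholded) plus a focal term α(1−p_t)^γ(−ln p_t) averaged over
pixels and channels, with p_t = P where G = 1 and 1−P where G = 0, and
α = 0.25, γ = 2. The focal term uses the natural log, following the
focal-loss literature. The loss is non-negative and → 0 exactly at a
confident perfect fit. An analytic gradient (verified against finite
differences in the test suite) backs the reference segmenter's training.

## Synthetic phantoms

Each phantom is one "patient": a jittered filled ellipse (femoral head)
partially seated in an annulus sector (acetabular crescent) opening
toward it, on a darker background, with additive Gaussian noise. Defaults
— 64×64 pixels, contrast 0.30, noise σ 0.08, N = 202, 15/15/3% splits —
make a low-contrast, noisy corpus whose femur and acetabulum masks
overlap in ≥95% of samples, reproducing the narrow-gap, overlapping-bone
structure that motivates multi-label masks. The cup's inner radius is
0.72 of the femur radius and its center sits 0.35–0.55 femur-radii above
the head's center, which is what guarantees the overlap. Optional clone
groups (exact duplicate images) give diversity queries a collapsible
structure to detect. 544×448 rendering is available via parameters;
resizing uses bilinear interpolation for images and nearest neighbor for
masks (keeping them strictly binary). Everything is a deterministic
function of (parameters, seed).

What the phantoms do **not** emulate: anatomical shape variability,
imaging physics (scatter, beam hardening), pathology grades, and
inter-annotator noise. Passing benchmarks here demonstrates the
correctness and end-to-end behavior of the AL machinery, not clinical
performance.

## Reference segmenter

The queries only require the segmenter contract (train / predict with
two sigmoid channels / seeded stochastic predict / a dropout flag), so
the shipped model is deliberately small: each pixel is described by 8
features (intensity; Gaussian blurs at σ = 1, 2, 4; their
difference-of-Gaussians; Sobel gradient magnitude; normalized row and
column), mapped by one hidden layer (24 units, leaky ReLU, inverted
dropout at rate 0.25) to the two channels. Leaky rather than plain ReLU:
with aggressive Adam steps a fully dead hidden layer is an absorbing
state from which a plain-ReLU model cannot recover. Training uses Adam
(lr 1e-2, batch 8 images) on the dice+focal objective under the standard
callback harness — learning rate ×0.1 after 8 epochs without validation
dice improvement (min delta 1e-4), early stop after 10 — and restores
the best-validation-epoch weights at the end. Monte Carlo Dropout draws
a fresh dropout mask per pass; the first-layer product is shared across
passes since dropout acts after the hidden activation.

## Problem sizes and numerical choices

The desk-scale benchmark (the `simulate` command, the end-to-end test
and the acceptance script) runs the full five-query experiment at
N = 202 phantoms of 64×64, n = 15, k = 30, 3 repeats, with training
capped at 50 epochs and each training step subsampling 25% of each
image's pixels (a cheap pixel-level SGD; the dice sums run over the
subsample). These sizes are the package's own choice to keep a complete
experiment around a quarter hour on one CPU; at them the averaged curves
rise from ≈0.3 (6 labels) to ≈0.91 test dice at pool exhaustion,
matching the fully-supervised upper bound trained on all 142 trainable
images. The per-repeat training-harness defaults in `TrainConfig`
(500 epochs, full-pixel batches) reflect the full-scale protocol.

Ties everywhere break by stable input order. Seeds derive from the
master seed via `numpy` `SeedSequence` with fixed counters, so repeats
are independent but the experiment is reproducible bit-for-bit; query
wall times are excluded from the dice CSVs so identical seeds give
byte-identical result files. Probabilities are validated into [0, 1] at
every module boundary.

## Known limitations

- The small segmenter's query ordering need not replicate large-model
  behavior: with 64×64 phantoms the informed queries and the random
  baseline converge to similar ceilings; superiority of informed queries
  is reported by the benchmark, not asserted.
- The feature space for the diversity queries is raw (optionally
  thumbnailed) pixels; learned embeddings are out of scope.
- One-cluster centroids are computed as means rather than via K-Means++
  runs; this is exact for the converged case but removes any
  initialization stochasticity a literal re-run would have.
- DICOM reading is a soft dependency (pydicom) and windows each image to
  [0, 1] by min-max; no modality-specific windowing.
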