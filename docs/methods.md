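# Methods

## Problem setting and model

A spatial-transcriptomics (ST) sample is a set of spots, each with a patch
image p (3×H×W, spot-centered), an expression vector e over d genes, and —
when produced by an upstream deconvolution tool — a nonnegative cell-type
abundance vector y over k fine-grained types (absolute scale; rows need not
sum to 1). The package learns F: p ↦ ŷ by exploiting paired (p, e) data at
training time only.

The gene view entering the model is h = ψ(e): the expression vector
normalized (each spot scaled to the median spot total, then log1p) and
subset to the r most highly expressed genes, ranked by total counts summed
over training-split spots, ties broken by gene index (default r = 250; the
reference experiment uses r = 100). Ranking on the training split only and
carrying the frozen index list inside the model checkpoint removes any
possibility of selection leakage into validation/test slides.

Two branches embed the modalities into a shared space of width d_a
(default 256):

- **Morphology** g = P(T(p)). T is a pluggable backbone behind
  `BackboneSpec`; the built-ins are `tiny_cnn` and `tiny_vit`. P is a
  2-layer projection head (hidden 512, SELU).
- **Molecule** s = H(S(h)). S is a self-normalizing MLP (default
  r → 256 → 256): SELU activations with the standard fixed-point constants
  (α ≈ 1.6733, λ ≈ 1.0507), lecun-normal initialization (std = 1/√fan_in),
  and alpha-dropout 0.1 active only in training. At initialization an
  8-layer stack holds activation mean within ±0.2 and variance within
  [0.5, 2] on standardized inputs (tested). H mirrors P.

Two heads close the objectives: an abundance regressor A (d_a → 256 → k) on
g, and an expression decoder G (d_a → 256 → r) on s. The abundance head is
unconstrained during training (the labels are nonnegative reals but the
loss is plain RMSE); predictions are clamped at zero only when exported for
spatial analysis, and the result object flags this.

### Losses

All three terms share one RMSE convention — the root of the mean squared
residual over **all scalar elements** of the batch (B·dim). The alternative
reading (root of the mean of per-row norms) differs only by a constant
√dim factor absorbable into the weights; the element-mean form keeps the
three terms on comparable scales across d_a, k and r, so the default
weights λ_C = λ_A = λ_G = 1 are meaningful. The total is
λ_C·L_C + λ_A·L_A + λ_G·L_G; L2 regularization enters through the
optimizer's decoupled weight decay, not the loss scalar.

Alignment-loss variants for ablation: plain MSE; a symmetric KL divergence
between row-softmaxed embeddings (raw embeddings are not distributions, so
softmax supplies the simplex mapping); and a symmetric infoNCE over the
B×B cosine-similarity matrix with temperature 0.07 (the standard
contrastive default). The gradient of the RMSE terms is undefined at an
exactly matched pair; this point is never reached during optimization.

### Backbones, LoRA, training loop

`tiny_cnn` (the default and the backbone of the reference experiment) maps
the image to optical density (−log transmittance, the standard stain-
quantification representation, so stain contributions combine additively),
applies three stride-2 SELU conv blocks (16/32/64 channels), and
concatenates the global average pools of all three stages with a
per-channel standard-deviation pool of the last stage before a linear head
(feature_dim 128). The multi-scale and second-order pooling matter: mean
color alone spans only three dimensions, while k > 3 cell types must be
separated; stage-wise means and channel variances carry the size and
covariance structure that identifies them. `tiny_vit` is a minimal
transformer (8-px tokens, two pre-norm single-head blocks, mean pooling)
exposing attention projections for LoRA; both satisfy the same interface
contract (tested).

LoRA wraps selected linear layers with W + (α/rank)·A·B, A lecun-normal,
B zero — so a freshly wrapped backbone is bit-identical to the unwrapped
one — freezing everything else. Defaults: rank 8, α 16, dropout 0;
targets are the attention q/v projections for transformers and the final
linear head for the CNN. Foundation-model backbones plug in as user-supplied
modules behind the same spec; none are bundled.

Training uses AdamW (lr 1e-3, weight decay 1e-2, betas 0.9/0.999) with
seeded shuffling, batch 64, model selection by validation total loss
(training loss when no validation slide exists) and early stopping at
patience 10. The learning-rate default is deliberately higher than typical
GPU fine-tuning recipes: a 400-spot slide at batch 64 gives ~6 optimizer
steps per epoch, and 1e-4 demonstrably underfits within a 20-epoch budget.
The entire run is deterministic given the config seed (numpy single-thread;
retraining reproduces the final loss bit-for-bit, tested).

Inference is image-only by construction — ŷ = A(P(T(p))) — and a tripwire
test substitutes an object that raises on any access for the expression
matrix to prove the path never reads it.

## Synthetic data generator

The generator emulates the structure the method relies on, at desk scale,
fully determined by one seed.

**Geometry.** An n_rows × n_cols hex grid (odd rows offset half a column),
default 20×20 = 400 spots, 80 px spacing at "full resolution".

**Study vs slide.** Signature matrix, rendering palette and per-type
amplitude scales are cell-type properties, so `gen_study` draws them once
per study and shares them across slides — as in a multi-slide Visium study
deconvolved against one scRNA reference — while spatial fields, count noise
and renders are per-slide (seeds spawned via `SeedSequence`).

**Abundances.** Per type, a Gaussian-process draw on the grid (squared-
exponential covariance, lengthscale 2 grid units), standardized,
exponentiated, and scaled by the type's amplitude: smooth lognormal
surfaces. Amplitudes are 1 + Gamma(α_d, 1) with α_d = 2 (`dirichlet_alpha`),
i.e. a shifted Gamma: heterogeneous across types, but floored so every type
renders enough nuclei to remain observable — an amplitude near zero would
make that type unlearnable from patches by construction and break the
generator's purpose of giving every downstream component signal to recover.
The lengthscale default balances two constraints: strong spatial
autocorrelation (per-type Moran's I ≈ 0.8 at 400 spots) against effective
sample size — much longer lengthscales leave so few independent field
values per slide that chance cross-type correlations (|r| up to ~0.7)
dominate what any model can learn from a single training slide.

**Expression.** Spot mean = abundance row · signature, globally scaled so
the average spot totals `count_depth` (1e4); counts are negative-binomial
via gamma-Poisson mixing with dispersion 10 (Poisson in the infinite-
dispersion limit, tested via variance/mean moments). The signature gives
each type r_signal = 5 dedicated marker genes enriched 10× over baseline —
the marker-gene structure that defines fine-grained transcriptional types.

**Patches.** Nuclei are filled ellipses scattered uniformly; each type's
nucleus count is Poisson with mean `nuclei_per_unit` (8) × local abundance,
so expected counts are exactly proportional to abundance. Rendering is a
Beer-Lambert stain model: each nucleus adds its type's absorbance to a
per-pixel optical-density map and the image is background · exp(−density).
Absorbances add — overlapping nuclei darken rather than occlude — so the
log-image is linear in per-type nucleus coverage and patch statistics are
sufficient for the abundance vector up to counting noise. Types are
identified by hue (HSV wheel), a unique nucleus radius (1.4–3.5 px,
interleaved against hue order so neighboring hues differ strongly in size),
and stain intensity ∝ 1/area (capped), which equalizes per-nucleus optical
energy: small-radius types render dark and dense, large-radius types pale
and broad, as lymphocytes vs epithelial cells do. The joint (hue, size,
darkness) code is what lets k > 3 types be separated despite a 3-channel
color space. Images are quantized to 8 bits so the PNG round-trip is exact.

**What it does not emulate.** Real H&E appearance (stain variation,
texture, stromal architecture), segmentation-relevant nuclear morphology,
batch effects, spatial expression artifacts, or dropout beyond NB noise.
Passing the recovery experiment therefore shows the architecture, losses,
training loop and evaluation machinery work end-to-end on data whose
morphology genuinely encodes composition — it does not certify performance
on real slides, where the morphology-composition link is weaker and
backbone quality dominates.

## Spatial evaluation

- **Weights:** symmetric union of directed 6-NN on spot coordinates
  (matching hex geometry; modal binary degree 6 on a hex grid, tested),
  then row-standardized. Note row standardization preserves weight symmetry
  only when degrees are equal (e.g. ring or interior hex); the
  co-localization matrix is symmetric exactly when W is.
- **Bivariate Moran's R** = z_aᵀ W z_b / n with population-std z-scores.
  With a = b this is univariate Moran's I, and on a 4-node alternating ring
  it is exactly −1 — the convention is pinned by these two identities and a
  brute-force double-loop oracle (tested to n = 200). Invariant to positive
  affine transforms of either argument.
- **JSD** is computed per cell type across spots (matching per-type
  reporting): each type's truth and prediction profiles are normalized to
  sum 1 and compared with base-2 Jensen-Shannon divergence, giving [0, 1];
  negative predictions are clamped first. Degenerate profiles: both all-zero
  → 0; exactly one all-zero → 1. A per-spot-across-types variant is not
  provided as a default because aggregate tables report per-type rows.
- **Correlations:** Spearman ρ with the two-sided t-approximation p-value
  and Pearson r per type; constant columns are reported as missing and
  excluded from the unweighted across-type means.
- **Co-localization:** the k×k matrix of pairwise bivariate Moran's R
  (diagonal = per-type Moran's I), optional average-linkage clustering on
  correlation distance for heatmap ordering; truth and prediction matrices
  are compared by Spearman ρ and cosine similarity of their off-diagonal
  upper triangles.

## Reference experiment and problem sizes

The acceptance script and end-to-end tests use a two-slide study at the
default generator configuration (400 spots/slide, k = 8, d = 300,
64×64 px patches), r = 100 retained genes, the `tiny_cnn` backbone, and
20 training epochs — sizes chosen so the complete experiment (data
generation, two training configurations, evaluation) runs in minutes on a
single CPU while leaving clear headroom between the recovered signal
(held-out mean ρ ≈ 0.55–0.59 across seeds) and chance. The cross-modal
configuration is compared against the morphology-only ablation
(λ_C = λ_G = 0) across three training seeds; the alignment and
reconstruction terms act as a regularizer on the shared representation and
consistently add a small positive margin on held-out recovery.

## Known limitations

- The numpy autograd runs on one CPU; wall-clock scales linearly with spot
  count and patch area. Foundation-scale backbones are integration points,
  not included, and would need their own runtime.
- Whole-slide image handling reads single-level arrays (TIFF/PNG) with an
  explicit scale factor; pyramidal level selection is the caller's choice.
- Moran's R significance (permutation tests) and spatially aware
  multiple-testing corrections are out of scope.
- The morphology-only ablation margin is modest on synthetic data by
  design: patches there are nearly sufficient statistics for abundance, so
  the molecule branch has limited extra signal to contribute.
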