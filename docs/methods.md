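# Methods

This note records the scientific and numerical choices behind `vesselseg`:
what each component assumes, which parameters matter, what the phantom
generator does and does not emulate, and where the design was genuinely open.

## Problem and model

Vessel segmentation is per-pixel binary classification of a fundus
photograph, with two structural difficulties: extreme class imbalance
(roughly one pixel in ten is vessel) and scale heterogeneity (vessel widths
span ~1–8 px in a full-resolution image). The architecture addresses the
second with multi-scale inception encoder blocks and with index-based
unpooling — the decoder receives the exact argmax locations of each 2×2
max-pool so thin-structure positions survive downsampling — plus
conventional concatenation skips. The loss addresses the first by
up-weighting misclassified vessel pixels.

### Decoder merge

The three decoder streams are (a) the transpose-conv upsampling of the
deeper features, (b) the index-unpooled map, (c) the encoder skip. Which
tensor is unpooled is an open design point: we unpool the *pooled encoder
map* with its own indices, which is the only channel-consistent choice
(indices and values then share the skip width) and reproduces the intended
semantics — the recorded window maxima return to their original positions,
zeros elsewhere. The streams are concatenated (3× skip width) and fused by
two 3×3 convs; a `merge_mode="sum"` variant adds the unpooled map into the
upsampled stream instead.

### Channel arithmetic

Encoder stage i outputs `base_channels · 2^(i-1)`; the bottleneck doubles
once more; decoder stage i returns to the mirrored width. Inception branch
widths for block output c are c/4 (1×1), c/2 (3×3), c/4 (stacked 3×3); the
1×1 reductions inside the two 3×3 branches compress to half the branch's
output width (standard inception practice; the reduction width is not
otherwise constrained). `base_channels` must be divisible by 4. All
convolutions are stride 1 with same padding: the alternative reading
(stride 2 inside the branches) would shrink the three branches unequally and
make concatenation impossible, so spatial reduction happens only in the
dedicated pooling op.

### Numerical core

No deep-learning framework is used. `vesselseg._nn` implements conv (as k²
shifted GEMMs), 2×2 transpose conv, batch norm, leaky ReLU, sigmoid,
max-pool-with-indices and index unpooling, each with a hand-written backward
pass, in float32 NCHW. Correctness is established in the test suite against
scipy correlation oracles and central finite differences (float64, interior
points). Two caveats are inherent to the architecture, not the
implementation: the loss is non-differentiable at the indicator threshold
p = 0.5, and index unpooling makes the output *discontinuous* in the
parameters wherever a pooling argmax ties — gradients are exact almost
everywhere, and finite-difference checks must use steps small enough not to
flip an argmax. Pool ties resolve to the first window position in row-major
order, for determinism. Weight init is He-uniform from a seeded generator;
a fixed seed reproduces runs bit-for-bit on a fixed BLAS.

## Loss

`J = α·L_dice + (1−α)·L_ce + (λ/2)·ΣW²`. The Dice term is the soft
(probability-weighted) relaxation with a smoothing constant (default 1e-6)
in numerator and denominator; it is computed per image and averaged, and the
hard set-based coefficient is available separately for evaluation. The
cost-sensitive cross-entropy multiplies the vessel log-term by
`1 + κ·I(p ≤ t)` with κ = 6, t = 0.5 — the literal product of the 2×2 cost
matrix (1, 6·I; 0, 1) with the per-class log-losses. A `penalty_mode=
"replace"` flag gives the alternative reading (weight exactly 6 when the
indicator fires). κ is a constant by design, never derived from class
frequencies. α is a fixed hyperparameter (default 0.5): treating it as
learnable without constraints would collapse onto whichever sub-loss is
cheaper. λ defaults to 1e-4 (conventional weight-decay scale); the L2 term
lives inside the loss, with λ·W added to each parameter gradient —
equivalent to optimizer weight decay under plain SGD. Logs are clamped at
1e-7 from both ends.

## CLAHE

Tile grid 8×8 (so a 512×512 frame gives 64×64 tiles), L = 256 gray levels,
clip coefficient α = 0.05. Per tile: T_clip = n/L + α·(n − n/L); total
excess above T_clip is N_tol; per-bin increment N_ace = N_tol/L; limit
T_lim = T_clip − N_ace; then h' = T_clip where h > T_lim, h + N_ace
otherwise — a single pass, so bins that land between T_lim and T_clip end
slightly above h + N_ace and total count is conserved only up to that slack
(bounded by L in practice on realistic histograms; asserted on 1000 random
histograms in the tests). The mapping is the clipped CDF scaled to
[0, L−1]; a tile whose raw histogram occupies a single gray level maps
identically, which makes the transform idempotent on constant images.
Per-pixel output blends the four nearest tile-center mappings bilinearly,
with clamped mappings beyond the border ring. Frames not divisible by the
grid are reflect-padded and cropped back.

## Augmentation

Four paired stages in narrative order — rotate (30° steps, identity
included, 12 orientations), mirror (original + flip), shift (one of four
corner directions, per-axis magnitude uniform in [20, 50] px), crop (four
random 512×512 patches) — each stage expanding the set, all multiplicities
configurable. Images interpolate bilinearly, masks nearest-neighbor (so
they stay binary), vacated regions zero-fill. "Toward a corner" is read as
one uniformly chosen diagonal sign pair with independent per-axis
magnitudes; the number of shift outputs per image is configurable
(default 1).

## Phantoms

The generator emulates what the method is sensitive to: dark curvilinear
trees (recursive random-walk branches, widths tapering within 1–8 px at
full scale, rescaled for smaller frames), vessel pixel fraction ≈ 12% of the
frame (trees are added until the FOV-clipped fraction reaches the target),
a smooth background with a radial vignette, additive Gaussian noise
(σ = 0.05 on the unit scale), vessel-background contrast 0.25, 8-bit
quantization, and a circular field of view. The truth mask is the exact
capsule-distance rasterization of the tree, captured before blur/noise.
It does **not** emulate: the optic disc and fovea, pathologies (exudates,
hemorrhages), color, inter-image illumination variation, or the spatial
statistics of real capillary networks. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that the method learns
low-contrast curvilinear structure under imbalance — not clinical-grade
performance on real fundus images.

## Training

Plain SGD (momentum available, default 0) with the step schedule
lr(e) = lr_init · decay^⌊e/every⌋; reference values lr 0.001, ×0.1 every
20 epochs, batch 20, 100 epochs. An epoch is one full pass over the
training set; batch order is drawn from the config seed; the
best-by-validation-Dice parameters are retained. A non-finite loss aborts
with epoch/batch/lr diagnostics rather than clipping.

Desk-scale runs use deliberately small problem sizes so the whole suite
runs on one CPU in minutes: the learning check trains a depth-2,
16-channel network for 30 epochs on 32 phantoms of 128×128 (lr 0.05,
momentum 0.9, batch 8 — a faster schedule suited to the small problem)
and reaches held-out soft Dice ≈ 0.78; the cost-sensitivity comparison
trains depth-2/8-channel twins for 25 epochs on 12 phantoms of 64×64 over
three seeds — a budget at which both arms have converged, so the
comparison probes the loss rather than transient under-training (at very
short budgets the plain-CE arm over-predicts vessels instead of
collapsing onto background, and the comparison is uninformative).

## Known limitations

- Batch norm uses per-batch statistics during training; with batch sizes
  of 4–8 the train/eval gap is visible in early epochs.
- The NumPy engine is single-threaded GEMM-bound; full-scale (565×584,
  depth-4, 100-epoch) training is out of its intended range.
- Checkpoints store raw float32 arrays plus a JSON architecture sidecar;
  bit-for-bit reproducibility holds only on the same BLAS build.
- AUC threshold sweeps cap at `n_thresholds` distinct values (default 256);
  exact Mann–Whitney equality requires the cap to exceed the number of
  distinct probabilities.
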