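# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `posam-ultra`, in the spirit of a methods appendix.

## The synthetic phantom generator

Real LGG slice collections pair FLAIR-like MR images with manually drawn
binary abnormality masks.  The generator emulates the features of those data
that drive this pipeline's behavior, at a size where full training runs fit
in seconds:

* a dark background (level 0.05) and a bright elliptical "brain"
  (level 0.35, semi-axes ~0.38H x 0.32W with ±5% jitter) with smooth
  low-frequency intensity texture (Gaussian-filtered noise, amplitude 0.06);
* one or more hyperintense elliptical tumor blobs placed fully inside the
  brain, jointly covering a configurable fraction of the frame
  (default 5%, the order of magnitude of visible abnormality in a
  tumor-bearing slice) at a configurable contrast above brain tissue
  (default +0.45, making the tumor the brightest tissue class as on FLAIR);
* three correlated channels with per-channel gains (1.0, 0.92, 1.08),
  standing in for the three stored image channels of the real data, plus
  i.i.d. Gaussian noise (default sd 0.03);
* the union of blob supports as the ground-truth mask.

Defaults: 64 x 64 pixels, one tumor, seed-deterministic.  What the phantoms
do **not** model: anatomical structure inside the brain (gyri, ventricles),
partial-volume boundaries, bias fields, motion artifacts, tumor-free slices
in sequence context, or inter-patient appearance shifts.  A model reaching
Dice ≈ 0.96 here has demonstrated that the architecture, losses, training
loop and metrics interoperate correctly — not that it would reach any
particular accuracy on clinical data.

## Preprocessing conventions

* Resize to a common square resolution (real data: 256 x 256); images
  bilinear, masks nearest-neighbor so they stay binary under "the same
  transformation".
* Min–max normalization to [0, 1] per image; a constant image maps to all
  zeros (the stable, order-preserving limit of the formula).
* Augmentation is sampled on the fly per training example: rotation up to
  ±20°, horizontal/vertical flips (p = 0.5), scale in [0.9, 1.1],
  brightness/contrast jitter ±0.1.  Geometric draws are applied identically
  to image, prior and mask; intensity draws only to the image channels (the
  prior is a likelihood, not an intensity).
* Split: |train| = floor(0.8 N); the remainder is divided evenly with the
  odd item going to validation — for N = 3,929 this yields exactly
  (3,143, 393, 393).  The split is slice-random, not patient-stratified
  (patient identity is not modeled).
* 8-bit mask files binarize at value > 127; row-major, origin top-left,
  0-based coordinates throughout.

## The prior channel

Brain-region estimation uses an automatic (Otsu) threshold on the
channel-mean image, keeps the largest 4-connected component and fills holes.
This is a classical intensity-based surrogate for dedicated neural
skull-stripping tools; it is exact on the phantoms and adequate on
high-contrast slices, but it is *not* a clinical skull stripper.

Within the brain mask, intensities are z-scored (mean 0, sd 1), clustered by
K-means with k = 3 (k-means++ seeding, 10 restarts, tolerance 1e-6, at most
100 Lloyd iterations, fixed seed — deterministic), and the cluster with the
highest mean intensity becomes the tumor candidate (ties break to the lowest
cluster index).  The candidate is cleaned by a 3 x 3 morphological closing
followed by a 3 x 3 median filter (the minimal structuring elements that
remove single-pixel noise and fill single-pixel holes).

A binary candidate is not a probability map, so it is softened: inside the
candidate the value is `0.5 + 0.5 · d/d_max` where `d` is the Euclidean
distance to the candidate boundary; outside it is 0; a final min–max maps
the result to [0, 1].  The 0.5 floor encodes that any candidate pixel is
more tumor-like than any background pixel, while the gradient to 1.0 at the
blob core expresses growing confidence away from the uncertain boundary.
(A plain normalized distance map would average only ~1/3 inside a disc,
diluting the candidate/background contrast the channel exists to provide.)
The prior is recomputed identically at training and inference time, per
slice.  K-means can converge to different local optima on different
intensity distributions; the fixed seed makes this reproducible, not
optimal.

## Network

* Stem: 7 x 7 conv, stride 2, no bias (batch norm absorbs shifts), BN, ReLU,
  2 x 2 max-pool — input resolution /4, `base_filters` channels.
* Encoder: `n_stages` DownBlocks; stage l carries `base_filters · 2^(l−1)`
  channels, stages beyond the first halve resolution via a stride-2 first
  conv.  Every DownBlock ends with CBAM and 2-D channel dropout.
* CBAM reduction ratio defaults to 16 (the common setting for 32+ channel
  models); the tiny 8-filter configuration uses 4 so that the bottleneck
  stays at least one unit wide.  Channel attention refuses C < reduction.
* Decoder: bilinear upsampling followed by a 3 x 3 conv (avoids the
  checkerboard artifacts of transposed convolutions); the matching encoder
  skip is attention-gated with the pre-upsampling deep feature as the gating
  signal; all shallower encoder maps are average-pooled down (never
  interpolated up) and 1 x 1-reduced to `base_filters` channels before
  concatenation, which bounds the fusion width; 3 x 3 fusion conv, CBAM.
* Head: after the gated stages (which end at 1/4 resolution) two plain
  upsample+conv stages restore full resolution; 1 x 1 conv + sigmoid.
* Deep supervision: auxiliary 1 x 1 conv + sigmoid heads on the decoder
  features at 1/4 and 1/2 resolution, bilinearly upsampled to the input
  size; λ₁ = 0.4, λ₂ = 0.2 by default (the deeper, blurrier head weighted
  less).  Auxiliary heads are skipped entirely in inference mode; with batch
  norm in eval mode, training-mode and inference-mode forward passes produce
  identical main outputs.
* Input contract: square inputs divisible by `2^(n_stages+1)`; prediction
  reflect-pads arbitrary sizes and crops back.
* Initialization: Kaiming-uniform from a single seed, so models are
  bit-reproducible.

The network and its training run on a package-internal reverse-mode autodiff
engine (float64 numpy: im2col convolutions, batch-norm with full backward
through the batch statistics, exact argmax max-pooling, dense-operator
bilinear resampling).  Gradients of every operation are verified against
central finite differences in the test suite.  This keeps the package
dependency-free beyond the scientific Python stack and makes CPU runs
exactly reproducible; the cost is speed, which the desk-scale problem sizes
are chosen to absorb.

## Losses

`L = w_bce·BCE + w_dice·Dice + w_focal·Focal` on the main and both auxiliary
outputs, combined as `L_main + λ₁ L_aux1 + λ₂ L_aux2`.  Predictions are
clamped to [1e-7, 1−1e-7]; soft Dice uses smoothing 1.0 (both-empty pairs
score zero loss); focal defaults are γ = 2, α = 0.25 (the community
standard; with γ = 0 and α = 0.5 the focal term reduces to BCE/2, a useful
identity check).  The tuning space carries one weight per term on [0.1,
0.9]; the weights are not forced to sum to 1 — the optimizer sees the scale
through the learning rate anyway.  A "boundary loss" is not implemented as a
separate term; the focal term is the third member of the composite.

## Polar-bear foraging optimization

Mixed dimensions are embedded in a continuous latent space: log-scaled
dimensions (learning rate, weight decay) are searched in log10 units,
discrete sets snap to the nearest listed value at decode time, categorical
dimensions round a [0, K) latent to an index.  Defaults: m = 20 candidates,
linear schedules α 1.0→0.2, β 0.8→0.1, γ 0.1→0.9, exploit probability
t/T_max, five-iteration grace period before the stagnation test
|Δf_best| < ε.

Moves are accepted **greedily**: a candidate that proposes a worse position
keeps its previous one.  With unconditional acceptance the late contraction
phase collapses the whole population onto the incumbent best and the search
stalls at whatever precision the population had at collapse time; greedy
acceptance preserves the diversity that the differential exploration term
feeds on, and on the 5-D sphere benchmark it moves final accuracy from
~1e-2 to ~1e-4–1e-7 at identical budgets.  The population is re-scored
every iteration, so noisy (training-based) fitness landscapes are re-sampled
rather than trusted once.

Dropout is tuned on [0.1, 0.5].  Fitness for real tuning is the validation
Dice of a reduced-budget proxy training run (budget is a caller-supplied
parameter); an analytic surrogate replaces training for benchmarks.  A
non-finite objective value records fitness 0 — the "diverged training run"
convention — rather than raising.

## Metrics

* Dice and IoU with the convention that two empty masks agree perfectly
  (1.0) and empty-vs-nonempty scores 0; zero-denominator confusion ratios
  return 0, never NaN.
* Boundaries are 4-connectivity erosion differences; distances are
  Euclidean, in pixels.  HD95 is the max of the two directed 95th-percentile
  distances; ASSD the mean and MSD the median of the distances pooled over
  both directions (all three therefore symmetric).  The median is reported
  as "MSD" because a robust central statistic is the only reading under
  which a median far below the mean is informative; the pooled mean is ASSD
  itself.
* SSIM uses a 7 x 7 Gaussian window (σ = 1.5), k₁ = 0.01, k₂ = 0.03, data
  range 1, and is computed between the binarized predicted and ground-truth
  masks.

## Training protocol

Default: 50 epochs, batch 8, Adam at 1e-3, step learning-rate decay ×0.5
every `lr_decay_step` epochs (the decay factor is a package choice; the
tuned quantity is the step), early stopping on validation Dice with the
configured patience, checkpoint overwritten on every improvement.  Momentum
applies only to SGD.  Validation and test predictions always run in
inference mode at threshold 0.5.  Runs are fully deterministic per seed
(data order, dropout, augmentation draws and initialization all derive from
explicit generators).

## Desk-scale benchmarks

Two seeded experiments (in `posam_ultra.benchmark`) exercise the system end
to end at sizes chosen so a complete run takes about a minute of CPU:

* **Overfit smoke test** — tiny network (8 filters, 3 stages, dropout off),
  one phantom, 200 Adam steps at lr 2e-3: the model must memorize the slice
  (train Dice ≥ 0.95).  Dropout is disabled and the rate raised relative to
  training defaults because the fixture tests memorization capacity, not
  generalization; channel dropout on an 8-filter model is large multiplicative
  noise that makes a 200-step check flaky without testing anything extra.
* **Desk-scale study** — tiny network with dropout 0.1, 200 training / 20
  validation / 50 test phantoms, up to 15 epochs with default training
  settings; typical held-out performance is Dice ≈ 0.96, IoU ≈ 0.93,
  HD95 ≈ 1 px.

## Known limitations

* 2-D slices only; no DICOM ingestion, no patient-level splitting, no
  multi-class (sub-region) output.
* The brain-mask surrogate assumes the brain is the dominant bright
  component; it will fail on images where that does not hold.
* The autodiff engine is single-threaded numpy; wall-clock scales roughly
  linearly with pixel count x filters², so the realistic 256 x 256 / 32+
  filter regime, while functional, is slow on CPU.
* The phantom benchmark's near-ceiling scores reflect the simplicity of the
  synthetic task, not expected clinical performance.
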