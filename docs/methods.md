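# Methods

This note records what the package computes, the modelling choices behind
it, and the conventions a user must know to interpret the outputs.

## Task and data model

The study object is a binary classifier for vertebral compression
fractures on grayscale radiograph crops, together with visual evidence for
its decisions. Real clinical data cannot ship with the package, so all
experiments run on a **synthetic generator** that reproduces the
statistical structure the pipelines care about, not radiographic realism:

- Each image is a bright, textured, convex quadrilateral ("vertebral
  body") over correlated noise, with nuisance variation in scale, gamma,
  blur, and an occasional bright occluding bar.
- Positive samples carry a wedge-shaped intensity defect crossing the
  body's cortical margin — the geometry of a compression fracture — and
  the wedge is recorded as the ground-truth lesion mask.
- `difficulty="easy"` (the default study condition) uses strong defect
  contrast and mild blur so that a miniature CNN can learn the task in
  seconds; `"hard"` reduces contrast and increases nuisance strength.
- Simulated annotators degrade the true mask pixel-wise (keep a lesion
  pixel with probability *sens*, flip a background pixel with probability
  *1 − spec*), optionally followed by morphological closing/opening so
  masks resemble hand-drawn regions. With smoothing disabled the Bernoulli
  operating point is exact, which the calibration tests rely on.

Every generator is a pure function of its arguments and a seed
(`numpy.random.SeedSequence`), so all results are bit-reproducible.

**Limits.** The generator does not emulate anatomy (no endplates,
pedicles, adjacent vertebrae), scanner physics, or reader search
behaviour. Conclusions about *directions* (e.g. "faithful maps beat random
maps", "positive maps cover lesions better than negative maps") transfer;
absolute numbers do not.

## Classifier

A miniature stand-in for large residual backbones: four blocks of
3×3 conv → ReLU → 2×2 max-pool with channels (8, 16, 32, 32), global
average pooling, and a two-neuron linear head. The third and fourth block
outputs are exposed as the **AM3** (8×8 at side 64) and **AM4** (4×4)
feature levels. The problem sizes are deliberately small so the full study
runs on one CPU in minutes; they are this package's choice, sized to the
synthetic task.

Training minimises class-weighted cross-entropy (Adam, default 30 epochs,
batch 16, lr 3e-3). The returned checkpoint is the epoch with the best
validation value of the configured objective (accuracy, sensitivity or
specificity), ties broken by higher accuracy, then by the earlier epoch.
The sensitivity-optimised variant combines class weights (1, 2) with
sensitivity checkpointing; the specificity-optimised variant mirrors that.
The networks are implemented in a small pure-numpy engine with manual
backpropagation (the environment provides no deep-learning framework);
convolutions are im2col + one GEMM, and the engine is single-threaded
deterministic.

## CAM algorithms

Given a tap's activations A (K, h, w) and the gradient G = ∂s_c/∂A of the
explained class score:

- Grad-CAM: per-channel weight = spatial mean of G_k; map = Σ_k w_k A_k.
- HiResCAM: map = Σ_k G_k ⊙ A_k (keeps spatial gradient detail).
- Grad-CAM++: closed-form weights from g², g³ (activations must be
  post-ReLU).
- XGrad-CAM: weights Σ(G_k ⊙ A_k)/ΣA_k.
- LayerCAM: Σ_k ReLU(G_k) ⊙ A_k.
- RandomCAM: i.i.d. uniform noise — the sanity-check reference.

Rectification happens in post-processing, not in the raw formulas, so
raw maps keep a uniform sign convention. Post-processing: ReLU →
corner-aligned bilinear upsample to the image resolution → min-max
normalisation to [0, 1]. An identically zero map stays zero; a constant
non-zero map (up to float jitter) becomes all ones. The map normalised at
the tap's native resolution is kept alongside, as the autoencoders'
regression target.

At the head-feeding block (AM4) the gradient is spatially constant per
channel (it equals the head weight over the pooled area), so Grad-CAM and
HiResCAM coincide exactly there; the test suite asserts this
architectural identity.

## Faithfulness metrics

- **Drop / increase**: mask the image by its map (Hadamard product) and
  compare the explained class's softmax confidence before (Y) and after
  (O): drop = mean max(0, Y−O)/Y, increase = fraction with O > Y.
- **ROAD-style score**: for each fraction p in {0.2, 0.4, 0.6, 0.8},
  remove the most-relevant (MoRF) and least-relevant (LeRF) p of pixels by
  map value and impute them with a **noisy linear infill**: every removed
  pixel is constrained to the mean of its in-grid 4-neighbours (retained
  pixels act as Dirichlet data), the sparse discrete-harmonic system is
  solved exactly, and zero-mean Gaussian noise (σ = 0.01) is added to the
  imputed pixels only. The per-image score is the mean over p of
  (conf_LeRF − conf_MoRF)/2; a faithful map scores high, a random map
  near zero. Ranking ties are broken by row-major order (stable sort), so
  constant maps are well defined.
- **Sanity check**: a candidate algorithm passes iff its ROAD strictly
  exceeds RandomCAM's under the same configuration.

## Evidence pipelines

Each pipeline emits the 4-map bundle {positive, negative} × {AM3, AM4}:

1. **single-model** — one classifier; maps for both output neurons.
2. **dual-model** — positive maps from the sensitivity-optimised model's
   fracture neuron, negative maps from the specificity-optimised model's
   no-fracture neuron.
3. **generative** — four autoencoders (one per polarity/level) map the
   feature tensors of a shared classifier straight to saliency maps,
   trained to imitate the single-model HiResCAM maps.

## Map autoencoders

Architecture: per-channel input standardisation (training-set statistics,
stored with the model) → two full-resolution 3×3 conv + LeakyReLU stem
layers → a two-stage avg-pool/conv encoder to a bottleneck (global context:
CAMs are normalised per image) → a resize-conv decoder (nearest upsample +
conv, which avoids the checkerboard artifacts of transposed convolutions)
→ skip-sum with the stem → 1-channel head.

Teacher maps are max-normalised, so the regression only needs to be right
up to a positive scale. Training therefore uses a **scale-invariant
two-phase loss**: a smooth L2-direction loss (MSE between the
L2-normalised rectified output and the L2-normalised teacher) for the
first 80 % of epochs, then a polish phase on the max-normalised MSE, which
is the reported metric. Rationale, found empirically on this task: the
max-normalised loss has a sharp argmax pivot whose subgradient traps a
noticeable fraction of random initialisations in poor basins; the
direction loss is smooth wherever the rectified output is non-zero and
removes that failure mode. Input standardisation matters for the same
reason — the feature channels' scales vary from 0 to ≈2.4, which badly
conditions the loss surface. Samples whose output is entirely rectified
away receive the raw residual as a fallback gradient so they can recover.
By default the loss is computed against the teacher at its native tap
resolution (interpolation artifacts would otherwise dominate); a config
flag switches to full-resolution targets via stateless nearest-neighbour
doubling.

## Consensus and agreement

- **fill_holes**: flips background components not touching the border
  (scipy's binary_fill_holes), applied to annotator masks before fusion.
- **STAPLE**: EM estimation of a latent truth together with each rater's
  sensitivity p_j and specificity q_j. Prior: spatially uniform scalar,
  the mean rater foreground fraction (the original's common variant; a
  spatially varying prior is out of scope). Initialisation
  p = q = 0.99999; E-step in log space; convergence when the largest
  parameter change drops below 1e-7 (max 100 iterations). Posterior ≥ 0.5
  is foreground (ties → foreground). Unanimous inputs short-circuit to
  the common mask. The implementation is cross-checked against SimpleITK's
  STAPLE in the test suite.
- **Kappa**: Fleiss' κ with items = pixels pooled across all study
  images (one κ for the whole study; per-image values are also emitted
  for diagnostics), categories = {background, foreground}; Cohen's κ on
  the 2×2 pixel table of two masks (e.g. specialists' vs residents'
  consensus). Degenerate single-category inputs are rejected rather than
  silently returning 0/1. Cross-checked against statsmodels.
- **Map binarization**: strictly greater than mean + one population
  standard deviation, so constant maps yield empty masks.
- **Overlap**: IoU and IoGT (= |mask ∩ gt| / |gt|) of the binarized map
  against the consensus mask, averaged per image then across images for
  every (approach, level, polarity). IoU ≤ IoGT always holds (the union
  contains the ground truth); IoGT is undefined (error) for empty ground
  truth. Only positive-labeled images enter the study.

## Numerical and reproducibility conventions

- Masks: row-major boolean arrays, origin top-left, aligned grids — no
  registration. On disk 0 = background, any non-zero = foreground.
- All randomness flows through `numpy.random.SeedSequence` with explicit
  stage seeds; string-derived seeds use CRC-32, never Python's randomised
  `hash()`.
- 2×2 max-pool ties route gradients to the first maximum in row-major
  order, keeping activation/gradient extraction deterministic.
- Report files carry a short SHA-1 hash of the run configuration;
  a run refuses to overwrite a directory holding artifacts from a
  different configuration unless forced.
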