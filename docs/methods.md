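# Methods

## Problem setting and model

The package addresses fine-grained identification of organisms whose labels
live in a three-rank hierarchy (family → genus → species). A flat softmax
over species ignores that hierarchy and can emit biologically impossible
chains; here the three ranks are predicted jointly and the hierarchy enters
in three places: the architecture (fusion), the loss (consistency
penalties) and the evaluation (alignment scores).

The classifier is: backbone convolutional features → Squeeze-and-Excitation
(SE) recalibration → global max-pooling → a shared dense embedding (ReLU,
dropout 0.3) → three parallel dense softmax heads. The SE block squeezes
each channel to its spatial mean, passes it through a two-layer bottleneck
(ReLU, then sigmoid; hidden width `channels/reduction`, reduction 16 by
default, floored at one unit) and rescales the channels by the resulting
(0, 1) weights.

Two backbones are provided. `small_cnn` (three 3×3 conv blocks, width
multiplier `base_channels`, ~25k parameters at the default width) exists so
the entire pipeline trains in seconds on one CPU. `resnet50v2` is a
pre-activation bottleneck ResNet-50 (stages 3/4/6/3, batch-norm, final
BN+ReLU, 2048 output channels) for full-scale work; no pretrained weights
ship with the package, so `pretrained=True` requires an explicit weights
file. The embedding width defaults to 2048 in `HierarchicalClassifier`
(matching the full-scale design) and to 256 in the `TaxonomicClassifier`
estimator, whose defaults target desk-scale data.

### Fusion strategies

All four variants consume identical inputs and emit identically shaped
prediction triples, so they are drop-in comparable:

- `std` — each head reads only the shared embedding.
- `concat` — the genus head reads [embedding, family logits]; the species
  head reads [embedding, genus logits]. Pre-softmax logits are used.
- `gated` — `fused = g ⊙ e + (1 − g) ⊙ t(parent logits)`, with `t` a
  transform of the parent logits and the gate `g` a sigmoid MLP over
  [e, t].
- `att` — a two-layer perceptron with sigmoid output maps the parent
  logits to a (0, 1) mask per embedding dimension, multiplied into the
  embedding.

The gate, transform and attention perceptrons are implemented as *narrow
bottleneck* MLPs (hidden width `max(8, embedding_dim/256)`). A full-width
dense gate over [e, t] would add ~8M parameters at embedding 2048 — a
~30% overhead that would confound the fusion comparison — whereas the
bottleneck keeps the gated/attention overhead below 1% of the standard
model's parameter count while preserving the gate semantics. The hidden
width is configurable (`fusion_hidden`).

Head weight matrices are initialised at 0.01× Glorot scale so an untrained
model emits near-uniform distributions over every label set while gradients
still reach the backbone. Argmax ties break toward the lowest index.

## Taxonomy-focal cross-loss

Per sample, with `p_t` the probability assigned to the true class at a
rank,

```
L_focal(p_t) = −α (1 − p_t)^γ ln p_t
L_fam = L_focal(p_fam[y_fam])
L_gen = L_focal(p_gen[y_gen]) + λ_gen · (−ln p_fam[par_gen(y_gen)])
L_spe = L_focal(p_spe[y_spe]) + λ_spe · (−ln p_gen[par_spe(y_spe)])
L_total = L_fam + L_gen + L_spe
```

The consistency penalty is *soft*: it bills the probability mass the parent
head places on the true label's parent taxon, not the argmax. Defaults are
the canonical focal setting α = 0.25, γ = 2 with λ_gen = λ_spe = 0.1; all
four are configurable and logged. Numerics: natural logarithms,
probabilities clamped at ε = 1e-7, batch reduction by arithmetic mean.
Labels inconsistent with the taxonomy raise a hierarchy-violation error
before any loss is computed. Two code paths share these formulas — a numpy
path on probability vectors (evaluation, worked values) and an autodiff
path on logits (training); tests pin them together and against
finite-difference gradients.

## Training protocol

Two stages: stage 1 trains the SE block, embedding and heads with
pretrained backbone layers frozen (15 epochs, Adam, lr 1e-3 by default);
stage 2 unfreezes the top `unfreeze_top_layers` backbone layers (75 by
default, counted from the output end of the backbone's layer enumeration,
clipped with a warning if it exceeds the depth) and fine-tunes (10 epochs,
lr 1e-5). The freeze applies to *pretrained* layers; a randomly initialised
backbone such as `small_cnn` has nothing to protect and trains end-to-end
unless `freeze_backbone_stage1=True` is forced. Optimizer choice and
learning rates are explicit configuration — they are package defaults, not
a claim about any particular historical run. All shuffling, dropout and
augmentation randomness derives from the config seed, so runs are exactly
reproducible.

Augmentation (training phase only, never materialised to disk) applies, in
order: random horizontal flip; rotation ±10% of a full turn (±36°, the
augmentation-layer convention for fractional rotation factors — the
interpretation is configurable); zoom in/out by a factor of 5–10%; contrast
±20% about the per-channel mean; additive brightness ±20%; translation
±10% per axis; a random crop to 352×352 (configurable); and additive
Gaussian noise σ = 0.2 on the [0, 1] intensity scale, followed by a clamp
to [0, 1]. Geometric transforms use reflect padding and bilinear
interpolation. Inputs smaller than the crop are reflect-padded with a
logged warning. Disabled, the pipeline is a deterministic bilinear resize.

## Quality control and splitting

- *Perceptual hash*: 8×8 average hash — BT.601 grayscale (0.299, 0.587,
  0.114), exact area-average resize to 8×8, bit i set iff cell i strictly
  exceeds the 64-cell mean (so a constant image hashes to all zeros). The
  average-hash variant was chosen for exact testability; near-duplicate
  threshold defaults: Hamming 0 for exact, 5 for near duplicates.
- *Dedupe*: greedy scan in id order; an entry is removed iff its hash is
  within the threshold of any previously kept entry. Idempotent on its own
  kept set.
- *Blur*: variance of the 3×3 Laplacian [[0,1,0],[1,−4,1],[0,1,0]] of the
  grayscale image (mirror boundary). Blur and resolution failures are
  *flagged* for manual review, never silently deleted.
- *Minimum count*: species with fewer than `min_count` (default 30) images
  are dropped; emptied genera/families are pruned from the taxonomy.
- *Split*: species-stratified 70/15/15. Per species, ids are shuffled with
  a per-species seeded RNG and allocated by largest-remainder rounding with
  a floor of one image per subset, so every species appears in train,
  validation and test. The rounding rule is a package choice; it yields
  14/3/3 for a 20-image species and exactly 70/15/15 for 100 images.

## Evaluation suite

- TAS = mean indicator that the predicted argmax triple satisfies both
  parent conditions; independent of label correctness. The random-consistency
  baseline for a uniform triple is `n_species / (n_fam · n_gen · n_spe)`.
- Per-rank metrics: accuracy plus macro-averaged precision/recall/F1 over
  classes present in the labels (macro because class imbalance is the
  motivating regime; micro is a switch).
- Alignment-given-miss: among samples wrong at a rank, the fraction whose
  predicted taxon shares the true parent; undefined (NaN + warning) with
  zero misses.
- Calibration: confidence = the head's argmax probability; ECE over 10
  equal-width bins (configurable), empty bins contribute zero.
- McNemar: exact two-sided binomial test on the discordant counts when
  b + c < 25, else χ² with continuity correction; b + c = 0 returns p = 1
  with a degenerate flag. Species-level correctness feeds the pairwise
  tests by default.
- Per-species error = 1 − recall, binned low (≤10%), moderate (10–25%],
  high (>25%); error-vs-genus-richness reports the OLS slope and Pearson r
  (NaN with a warning under zero variance).

## Guided saliency

Saliency targets the species head's pre-softmax logit (a linear readout,
sidestepping softmax coupling). Under the guided rule the backward signal
through every ReLU is zeroed wherever the forward activation *or* the
upstream gradient is negative. The per-pixel score is the channel maximum
of the absolute guided input gradient, min-max normalised per image
(constant maps become all zeros). Models without ReLUs fall back to vanilla
gradients with a warning. Overlays alpha-blend a configurable colormap
(default jet-like, alpha 0.5).

## Synthetic data generator

The generator emulates the nested factor structure real specimen imagery
possesses — coarse features shared within coarse taxa — so hierarchical
fusion has genuine signal to exploit: family fixes the body silhouette
(ellipse eccentricity and tail size), genus fixes the base hue (golden-ratio
spaced, saturation 0.85), species fixes a marking pattern (2–4 stripes or
spots, light or dark, from a fixed species-seeded stream). Bodies are
rasterised analytically in body-local coordinates, so markings follow the
body under jitter and exact body/marking masks are available
(`return_masks=True`).

Regimes: *lab* renders are centred (±4% jitter), sharp, on a near-uniform
background with a faint random shading gradient (a photo-tank lighting
analog that also makes distinct renders perceptually distinct); *web*
renders add low-frequency background clutter, ±18% placement and 0.55–0.95
scale variation, 0.6–1.1× lighting jitter and Gaussian blur (σ 0.9–1.6), so
web images score strictly lower on Laplacian sharpness than matched lab
renders. Taxonomy allocation guarantees every parent at least one child and
draws the rest from a Dirichlet-weighted multinomial so genus richness
varies. A `duplicate_fraction` knob injects exact pixel duplicates of
earlier same-species images (recorded in the manifest) and re-perturbs base
renders until their hashes are pairwise distinct, making duplicate-removal
behaviour exactly checkable.

What passing tests on this generator do *not* show: robustness to real
photographic nuisance (pose, occlusion, specularity, camera response),
realistic inter-species similarity structure, or any particular accuracy on
real fish imagery. The generator's factor assignment is deliberately
clean; it validates mechanism, not field performance.

## Problem sizes and numerical choices

Desk-scale test conditions: the end-to-end run trains `small_cnn`
(base width 8, embedding 64) on a 3-family/6-genus/12-species × 60-image
lab-regime dataset at 32 px, 12 epochs, for each of the four fusion kinds;
the data-regime comparison uses 24 images per species at 8 epochs. These
sizes were chosen as the smallest at which training visibly separates all
three ranks from chance. Everything runs in float64; gradient tests demand
finite-difference agreement at 1e-5 (engine) and 1e-4 (loss). Checkpoints
are .npz weight archives with a JSON sidecar recording taxonomy and
configuration.

## Known limitations

- The numpy engine is single-threaded and eager; it is sized for
  desk-scale experiments, not for 26k-image training runs.
- `resnet50v2` reproduces the pre-activation bottleneck structure but not
  the exact published layer enumeration (stride placement differs at stage
  boundaries), and no ImageNet weights are distributed.
- The 8×8 average hash is coarse: visually distinct low-resolution images
  can collide at Hamming 0, which is why the generator's QC mode enforces
  hash-distinct base renders.
- Saliency evaluation is structural (marking region vs background); no
  claim is made about agreement with expert-defined diagnostic traits on
  real organisms.
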