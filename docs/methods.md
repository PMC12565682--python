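# Methods

## Problem and model

Whole-body mouse radiographs from high-throughput phenotyping pipelines are
acquired in two standard projections — dorsoventral (DV, coronal) and
lateral (LAT, sagittal) — and annotated by experts with abnormality codes
from a fixed 53-observation vocabulary. `mvskel` addresses multi-label
skeletal-abnormality classification on these images at three nested
granularities:

* **L1**: a specimen is *abnormal* iff its code set is nonempty.
* **L2**: each code maps to one anatomical subclass in {Limbs, Ribcage,
  Skull, Spine, Whole-body}; a specimen's L2 label is the image of its code
  set under that map.  Skull and Limbs are excluded from the modelled set
  by default (abnormalities there are rare in full-body views), leaving
  three classes.  Codes in excluded subclasses still make a specimen
  L1-abnormal but contribute no L2/L3 bits.
* **L3**: each code also maps to one of ten finer classes
  (Caudal, Thoracic, Cervical, Lumbar, Morphology, Shape, Digits, Fusion,
  Joints, Other).

The retained L2 (3) and L3 (10) classes define a 13-slot binary label
vector per specimen (L2 slots first, then L3 in the canonical listing
order); a normal specimen is all zeros.  Specimen labels are the union of
image-level labels across all of a specimen's full-body images.

## Multiview composite

Each specimen is represented by one 3-channel image: the pixel-wise mean of
its DV acquisitions, the mean of its LAT acquisitions, and a weighted blend
of the Canny edge maps of those two means.  Averaging repeated acquisitions
suppresses acquisition noise; the edge channel injects explicit structural
cues from both projections into one plane.  Pipeline order: quality filter
(per-view intensity-outlier rule at k = 3 standard deviations, plus an
aspect-ratio band) → bilinear resize to a square grid with min-max
normalization → group by specimen, discarding non-full-body views and
specimens missing either view → per-view mean → Canny (σ = 1.0, hysteresis
thresholds 0.1/0.2 on [0, 1] intensities) → removal of edge components
under 10 px (8-connectivity) → blend with DV weight 0.6 → channel stack.
The DV weight is the minimal asymmetry honouring the preference for the
coronal projection; Canny parameters are standard defaults.  All parameters
live in `CurationConfig`.  The full-scale composite is 224×224×3; phantom
benchmarks use 64×64×3.

## Classifier families

Both families share the chained three-level shape: a shared trunk feeds an
L1 binary head; the L1 penultimate representation feeds the L2 head (three
independent sigmoids); the L2 penultimate feeds the L3 head (ten sigmoids).
Lower levels are frozen before a higher level trains, so learned features
are retained bit-exactly.  All heads train with Adam and binary
cross-entropy under validation-loss early stopping; L2/L3 heads train and
evaluate on abnormal specimens only.

* **Backbone family** — a convolutional feature extractor (any module
  producing a spatial feature map; the desk-scale default is a small
  trainable CNN with filters (8, 16, 32)) trained end-to-end with the L1
  head: GAP → dense(32, ReLU) → dense(1, sigmoid).  The L2/L3 heads reshape
  their input vector into the smallest even square-ish 3-D tensor (32 →
  4×4×2), then conv(32 filters, 3×3, ReLU) → max-pool → flatten → dense
  (128, 64, 32, ReLU, L2 weight decay 1e-4) → sigmoid outputs.  Reference
  per-level learning rates (0.001 / 0.0001 / 0.00011) are recorded in
  `REFERENCE_TRAIN_CONFIGS`.
* **CAE family** — a convolutional autoencoder (stacked conv+pool encoder,
  mirrored conv+upsample decoder) trained to reconstruct the composite
  under MSE; the reference configuration reduces 224×224×3 to a 56×56×128
  latent, the desk-scale configuration 64×64×3 to 16×16×32.  The decoder
  output is linear: with mostly-dark radiographs a sigmoid output saturates
  under MSE and stalls training; reconstructions are clipped to [0, 1] at
  evaluation.  L1 is a dense sigmoid probe (flatten → dense(32, ReLU) →
  dense(1, sigmoid)) on the latent, trained with BCE — the top-level
  classification mechanism for a reconstruction-trained model is otherwise
  unspecified, and a latent probe is the simplest supervised reading of the
  learned features.  The L2/L3 heads are dense-only stacks with dropout —
  widths (256, 128), rate 0.1.  We found narrower heads (128, 64) with
  dropout 0.3 cost roughly 0.05–0.1 mean AUC at desk scale, where only a
  couple of hundred abnormal specimens are available; the wider, lightly
  regularized heads are the package default.

### The neural-network engine

No deep-learning framework is used: the layers (im2col convolution, 2×2
max-pool, nearest-neighbour upsampling, dense, dropout, GAP), Adam, the
BCE/MSE losses and the early-stopping training loop are implemented
directly on numpy in `mvskel.nn`.  Parameters and activations are float32
(halving memory traffic in the memory-bound convolutions); losses
accumulate in float64.  All randomness — initialization, shuffling,
dropout — derives from seeded `numpy.random.Generator`s, so training is
bit-reproducible on a single machine.  Analytic gradients are verified
against central differences in the test suite.

## Synthetic phantom generator

The generator emulates the *structure* of multi-center phenotyping data —
two full-body views per specimen, 1–3 acquisitions per view, class
imbalance, co-occurring abnormalities, multiplicative per-acquisition
brightness jitter (±15%) and additive Gaussian noise (σ = 0.02) — not mouse
anatomy or X-ray physics.  A phantom is a parametric skeleton (spine of 20
vertebrae with separate coronal and sagittal offsets, 10 rib pairs, limbs,
skull ellipse, 12 caudal vertebrae) rasterized as bright strokes on a dark
background, Gaussian-blurred, with DV projecting the coronal plane (ribs,
limbs and digits are drawn here) and LAT the sagittal plane.

Each L3 class is a deterministic geometric edit with a declared view
visibility (see the table in `mvskel/synthetic.py`): cervical and lumbar
vertebral displacements are sagittal (LAT-only), thoracic coronal
(DV-only), rib fusion and limb-joint gaps DV-only, tail truncation, bone
thickening, body-axis compression and the pelvic blob visible in both.
Classes edited in one plane are **pixel-identical** in the orthogonal
noiseless render — the contract that makes multiview superiority testable:
a single view carries no information about the classes hidden in its
orthogonal plane.  Digit fusion carries a Limbs-subclass code, so it makes
specimens L1-abnormal while contributing no modelled label bits,
exercising the subclass-exclusion path end to end.

Abnormal specimens (probability `abnormal_fraction`, default 0.3) draw each
class independently from its prevalence (default 0.22 per class, digit
fusion 0.05), rejecting the all-empty draw; the exact conditional
frequency p/(1 − Π(1 − p)) is the oracle for the prevalence-recovery test.
Normal phantoms get mild benign geometric jitter so L1 is not a trivial
constant-image comparison.

What passing phantom tests does **not** show: robustness to real anatomical
variability, pathology appearance, occlusion, exposure artifacts, or
center-specific geometry — the phantom's nuisance model is far simpler than
real radiographs, and absolute AUCs here do not transfer.

## Evaluation protocol

Specimens split 70/20/10 (train/validation/test), stratified by L1 only
(preserving the imbalance without exploding empty strata), repeated over
distinct seeds (default five; the phantom benchmark uses three).  Per-class
ROC-AUC is the rank statistic (pairwise concordance, ties ½), threshold-
free, one-vs-rest on the sigmoid outputs; classes absent from a test split
are flagged missing and skipped (with a count) in the unweighted per-level
mean.  Reported values are across-seed means with across-seed standard
deviations.  The CAE family additionally reports reconstruction MSE and
SSIM (k1 = 0.01, k2 = 0.03, unit dynamic range, uniform 7×7 window) on the
held-out split.  View modes select composite channels: DV → channel 0,
LAT → channel 1, MV → all three; everything else (architecture, training
settings, splits) is identical across modes.

## The standard phantom benchmark

`evaluation.standard_phantom_benchmark()` fixes the package's working
conditions: 600 specimens at 64×64, abnormal fraction 0.5 (the generator's
general default of 0.3 mirrors the real imbalance; 0.5 at n = 600 keeps
~210 abnormal training specimens so the L2/L3 heads have data to learn
from), CAE family, three split seeds, five single-view-visible classes.
Desk-scale training: CAE reconstruction at learning rate 2e-3, ≤20 epochs,
batch 8; heads at 1e-3, ≤80 epochs, batch 16, patience 5.  The reference
full-scale rates (1e-4…1e-5), tuned for fine-tuning large pretrained
networks on tens of thousands of specimens, do not converge from random
initialization at this scale within any sensible epoch budget; the
desk-scale calibration is recorded in `ExperimentConfig` and used by the
benchmark, tests and acceptance script alike.  One full benchmark run takes
roughly 8–10 minutes on one CPU core.

## Decision interpretation

`compute_cam` implements the classic class-activation map: final conv
feature maps weighted per channel by the final dense layer's weights for
the requested class, summed, rectified (negative contributions are dropped
before normalization, preventing sign-cancellation artifacts), bilinearly
upsampled to the input size, and min-max normalized with a zero guard.  It
requires the final dense input width to equal the conv channel count (a
GAP-style head).  `gradient_cam` replaces the dense weights with spatially
averaged gradients of the class score, works for arbitrary heads, and is
what the CLI's `explain` command uses; the source layer is a parameter.
Overlays blend a perceptually-uniform colormap (inferno) at α = 0.4 by
default.

## Numerical choices and degenerate inputs

Min-max normalization maps constant images to zero.  Sigmoid
pre-activations are clipped at ±15 (beyond which float32 rounds the output
to exactly 0/1); BCE clips probabilities at 1e-7.  Max-pool gradient ties
share gradient equally.  Early stopping restores the best-epoch weights.
AUC with a single class present returns NaN (flagged missing), never an
imputed value.  Empty edge maps, all-zero composites and all-zero CAM
weights all produce well-defined zero outputs.

## Known limitations

* The phantom is structurally faithful but visually simplistic; absolute
  metrics on it are optimistic relative to real radiographs.
* The backbone family ships only with the small trainable CNN; pretrained
  ImageNet backbones can be plugged in behind the same interface but are
  not bundled.
* Across-seed standard deviations with three seeds are coarse.
* The L3 head inherits the L2 head's penultimate representation; if the L2
  head is trained to a degenerate optimum, L3 cannot recover (mitigated by
  the wider desk-scale heads).
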