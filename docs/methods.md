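# Methods

## Data model and preprocessing

A sample is a single 2-D slice of one modality (PET in normalized-uptake
units, CT in Hounsfield units) with a binary lesion mask, a patient
identifier and an optional benign/malignant label. PET and CT are treated as
independent unimodal samples sharing one mask per slice pair; no multimodal
fusion of the two images is performed. Preprocessing follows the clinical
pipeline the models assume:

- CT values are clipped to the [−150, 250] HU soft-tissue window (air and
  bone extremes carry no lesion information);
- PET intensities are normalized per image, min–max to [0, 1] (default) or
  z-score; a constant image maps to zeros so degenerate synthetic inputs
  cannot produce division by zero;
- in-plane resampling to an isotropic pixel size uses bilinear interpolation
  for images and nearest-neighbour for masks (masks stay binary). The target
  spacing is a configuration parameter with default 1 mm; no claim is made
  that this matches the original acquisition;
- lesion delineation from a PET region of interest thresholds at 40% of the
  ROI maximum uptake. True SUV conversion (dose/weight/decay) requires DICOM
  headers and is out of scope; the threshold operates on reconstructed
  intensities.

All distances are reported in pixel units after resampling. Masks use 1 for
lesion foreground, row-major 0-based indexing.

## Segmentation architecture

Two encoder–decoders with complementary receptive fields are trained as one
model:

- **U branch.** A stem convolution followed by four MobileNet-style
  inverted-residual stages (1×1 expand → 3×3 → 1×1 project, batch norm and
  ReLU between, residual shortcut where shapes allow), each with stride 2:
  spatial sizes halve from the input size S to S/16. The decoder performs
  four resize-up + skip-concatenation + convolution steps pairing the i-th
  decoder feature with the (5−i)-th encoder feature, ending at full
  resolution. Training is from scratch; no pretrained weights are claimed.
- **Kite branch.** The encoder *up*-samples: conv + batch norm + ReLU
  followed by spatial growth with factors (2, 2, 2, 1) — three doublings
  then a channel-only stage. Growing all four levels would multiply the
  input size by 16 and is memory-infeasible, hence the cap. Because the
  growing encoder is expensive, the branch receives a down-scaled copy of
  the input (128 px at full scale). The decoder mirrors the encoder,
  pooling back down via resize, with the same four skip concatenations.
  One decoder stage consumes each of R1..R4 in order.
- **Fusion head.** The kite output is resized up to the U branch's
  resolution, the two feature maps are concatenated along channels,
  projected by a 1×1 convolution to two class maps, resized to the input
  size, and normalized per pixel by softmax. Either branch can be disabled,
  yielding the single-branch ablation models under the identical head and
  training loop.

Up/resize interpolation is bilinear by default (nearest available); resize
is implemented as a pair of 1-D interpolation matrices applied to rows and
columns, which makes its adjoint (the gradient) exact.

Per-level channel widths are not dictated by the problem and default to
(16, 24, 32, 48, 64) for the U branch and a constant 8 for the kite branch
at full scale (512-px input, 128-px kite input). The desk profile — the same
topology sized for a single CPU — uses 128-px input, 16-px kite input,
channels (6, 12, 18, 24, 32) and 4. The kite input of the desk profile is
deliberately small: the growing encoder dominates compute and memory, and a
16→128 px growth keeps a training step under a second on one core while
preserving the overcomplete topology the branch exists to test.

## Loss

The compound loss is the α-weighted sum of cross entropy and soft Dice on
per-pixel class probabilities, α = 0.5. The Dice term averages per-image
ratios over the batch with an ε = 1e-5 stabilizer in numerator and
denominator (ε is not fixed by the source recipe; 1e-5 keeps the perfect
prediction's loss within 1e-4 of zero at desk image sizes). Probabilities
are clamped at 1e-12 before the logarithm. Two cross-entropy normalizations
are provided: `per_pixel_mean` (default) divides by batch size × pixels,
keeping the CE term on the same O(1) scale as the Dice term, which is what a
*balanced* compound loss requires; `paper_sum` divides by batch size only
(the literal printed form, N-fold larger) and is retained for fidelity
testing. The loss accepts plain arrays (returns a float) or autodiff
tensors (participates in backprop); both paths are tested against a literal
quadruple-sum evaluation.

## Augmentation

- **CarveMix** (segmentation): the lesion region of slice A, as delimited by
  A's mask, replaces the corresponding pixels of slice B — the same pixel
  coordinates, since pairs are co-registered in a common frame; there is no
  blending weight. The output mask is the union of the two masks, with A's
  lesion authoritative inside its own footprint (B's lesion survives outside
  the carve). Per-pixel provenance tags make the partition testable exactly.
- **Mixup** (classification): λ-convex combinations of image pairs and their
  one-hot labels, λ ~ Beta(α, α) with α = 0.2 (the mixing concentration is
  not fixed by the source recipe; 0.2 is the value commonly used for
  image classification and is configurable).
- **Basic**: random horizontal/vertical flips and rotation, default ±15°
  (range unspecified in the source recipe), bilinear for images and
  nearest-neighbour for masks.
- **M + kM expansion**: round(k·M) synthetic samples whose source pairs are
  drawn uniformly without self-pairing from the training fold only, so
  validation leakage is structurally impossible. Pairing is unrestricted
  across classes by default (configurable). Expansion is regenerated each
  epoch by default; a frozen mode fixes one expanded set per run.

## Cross-validation and training

Folds are patient-level: a patient's slices never span folds. Stratified
plans shuffle each class's patients by seed, order large patients first, and
assign each to the fold currently holding the fewest patients of that class
(ties broken by total image count), so per-fold class counts stay within one
of proportionality and image counts stay near-balanced. The true assignment
procedure behind the published tables is unknowable; this greedy rule
reproduces their near-equal distribution style.

Training uses AdamW (decoupled weight decay, default 1e-2 — unspecified in
the source recipe), learning rate 1e-4, batch size 16, 40 epochs with a ×0.1
decay every 10 epochs. The held-out fold doubles as the validation set for
model selection (best validation Dice for segmentation, best accuracy for
classification); the source recipe does not state a selection rule, so this
is an approximation, documented as such. Mixup training minimizes the soft-
label cross entropy. Desk-scale runs shrink epochs and batch size and raise
the learning rate (3e-3 segmentation, 2e-3 classification) to converge
within a CPU budget; the recipe itself is unchanged.

The classification backbone is a pluggable contract (any image → 2 logits
map); the provided `SmallConvClassifier` is three strided conv + batch-norm
+ ReLU stages with global average pooling and a linear head. It stands in
for the large pretrained families the published comparison used, which are
out of scope here; the contract is where such a backbone would plug in.

## Phantom cohorts

The generator emulates the structure the method assumes, not PET/CT physics:

- lesion geometry is a star-convex polygon, radius r(θ) = R·(1 +
  irregularity · Σ low-order cosine harmonics), rasterized and
  morphologically closed; one simply-connected lesion per slice, identical
  mask for both modalities;
- class contrast: benign lesions have low boundary irregularity (0.06) and
  lower PET uptake (mean 1.4 over a 0.25 background), malignant high
  irregularity (0.40) and higher uptake (mean 1.9); both classes get only
  mild random ellipticity (axis ratio 0.85–1.0), since stronger elongation
  would confound the circularity contrast; CT renders the same
  geometry as a mildly hyperdense lesion (+60 / +95 HU) over a textured
  soft-tissue background inside the clinical window;
- several slices per synthetic patient (3–6), additive Gaussian noise and a
  smooth low-frequency background field per slice; radii 6–20 px at the
  128-px default size.

The published study gives no lesion size/intensity statistics, so these
values are chosen for testability — a single circularity threshold separates
the classes with ≥90% accuracy, making the classification task learnable by
construction. Passing desk-scale tests therefore demonstrates that the
architecture, losses, augmentation and cross-validation machinery work and
interact correctly; it says nothing about absolute performance on clinical
PET/CT, where lesions are harder, multi-focal disease exists, and 3-D
continuity matters (all deliberately absent here).

One consequence of the phantoms' easiness: the U branch alone already
reaches held-out Dice ≈ 0.98 within a few epochs, so the fusion-vs-U-branch
comparison operates near saturation and their ordering is decided by
run-to-run noise of a few thousandths — the fusion model wins most seeds but
not all. The kite-only model stays clearly lowest at every budget, because
its down-scaled input and edge-focused receptive field cannot represent
whole-lesion extent; that part of the published ablation ordering is
reproduced robustly. Ablation runs therefore use a deliberately short budget
(4 of the 10 desk epochs) and report a majority over three seeds.

## Evaluation and statistics

Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B| on masks binarized at
probability 0.5; both-empty pairs score 1.0. The average Hausdorff distance
is the symmetric mean of directed nearest-neighbour Euclidean distances over
all foreground pixels (a boundary-only variant is available); an empty
prediction against a nonempty reference is penalized with the image-diagonal
length and flagged with a warning — a finite, monotone penalty in place of
an undefined value. Classification reports accuracy, rank-based AUC (ties
half-weighted), and sensitivity/specificity with malignant as the positive
class. Cross-fold aggregation is the arithmetic mean and sample SD (ddof 1),
rounded to 3 decimals for reporting. Model comparisons use two-tailed paired
t-tests on per-fold values (identical sequences give p = 1.0 by convention);
benign-vs-malignant sensitivity analyses use Welch's t-test.

The per-fold values of the published five-fold evaluation ship as package
data. Aggregation tests are restricted to internally consistent columns:
several printed AUC means (and one IoU mean) in the source tables do not
equal the mean of their own fold values and are not asserted.

## Numerical engine

`kitefusion.nn` is a reverse-mode autodiff on NumPy arrays with exactly the
primitives the models need. Convolution is computed as one GEMM per kernel
tap on shifted views of the padded input, avoiding the k²-fold im2col copy;
batch normalization is a fused primitive with the standard closed-form
backward; resize is linear, so its gradient is the transposed interpolation.
Float32 is the working precision for parameters; the graph preserves input
dtype, and the loss oracle tests run in float64. Every primitive's gradient
is tested against central finite differences, and the full model's loss
gradient is spot-checked the same way.

## Known limitations

- Phantoms are 2-D and single-lesion; no attenuation, partial-volume or
  reconstruction effects, no 3-D lesion continuity.
- The published headline numbers come from a private clinical dataset and
  GPU-scale backbones; desk-scale runs verify behaviors (learnability,
  branch ordering, augmentation non-degradation), not absolute values.
- Exact per-level channel widths of the published architecture are unknown;
  defaults are documented choices, not claims of fidelity.
- Training determinism holds for data order, initialization and
  augmentation given seeds; metric thresholds in tests are tolerance-based.
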