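# Methods

## Problem and pipeline

`hemocascade` implements a cascaded analysis of axial head CT for
traumatic brain injury (TBI): given a slice stack it (1) screens each
slice with a binary hemorrhage classifier, (2) segments hematomas with
a coarse-to-fine two-stage encoder-decoder cascade, (3) assigns the
five intracranial-hemorrhage subtypes (EDH, IPH, IVH, SAH, SDH) with a
multi-label classifier that fuses a mask-superimposed global view and a
local ROI view, (4) converts the emitted masks into hematoma volume in
millilitres, and (5) feeds volume and subtype indicators into
CRASH-style 14-day mortality models alongside clinical covariates.

Slices that fail the binary gate receive an empty mask and an all-false
label vector without invoking the heavier models; this mirrors the
cascade's efficiency rationale and is asserted by call-count tests.

## Two-stage segmentation

Stage I segments the full slice. Its thresholded output (threshold 0.5,
the same threshold used everywhere a probability is binarized) defines
a region of interest: the tight bounding box of all foreground pixels,
expanded to a square (odd leftover pixel to the high-index side),
grown by a 20-pixel margin — surrounding tissue context demonstrably
helps fine segmentation — and clamped to the image. The clamped
rectangle is kept as-is rather than shifted back inside, so a lesion
near the border stays centred; back-projection uses the recorded
clamped extent. The crop is resized to the working resolution
(bilinear for intensities, nearest-neighbour for masks, so labels are
never blended), segmented by Stage II, back-projected, and the two
probability maps are fused by a voting rule before the final
threshold. The default vote is the pixel-wise mean — symmetric, and it
reduces to either voter when they agree; union and intersection are
available for sensitivity checks. Stage II is trained on
ground-truth-derived ROI crops (empty slices are excluded), while at
inference the ROI comes from Stage I.

Both stages use Dice loss with smoothing epsilon = 1 in numerator and
denominator, which keeps empty-mask batches finite; on binary inputs
the loss equals 1 − Dice up to that smoothing, which the tests assert.

## Backbones and training

All trainable components run on a small self-contained NumPy layer
library (3x3 convolutions via im2col, instance normalization, ReLU,
2x2 max pooling, nearest-neighbour upsampling, global average pooling,
dense layers) with hand-written backward passes verified against
numerical differentiation, Adam, and a cosine-annealing learning-rate
schedule. Everything is float32, single-threaded and bit-reproducible
under a fixed seed; checkpoints round-trip to identical predictions.

The default `tiny` backbone family is sized for CPU desk scale:

* segmentation: a 3-level UNet (8/16/32 channels, skip connections,
  ~30k parameters) at 64x64;
* classification: conv8-pool-conv16-pool-conv32, pooled globally with
  the concatenated spatial mean and spatial max of each channel (a
  64-d view descriptor; the mean tracks lesion extent, the max tracks
  presence — pure average pooling proved unreliable for detecting
  small lesions at this scale). The binary filter is one backbone plus
  a logistic unit; the fusion classifier runs one backbone per view,
  concatenates the two pooled vectors and maps them with a single
  linear layer to five sigmoid outputs. A global-only ablation (one
  backbone) measures the contribution of the local branch.

Training presets: Adam, learning rate 1e-2 for the tiny backbones
(from-scratch training of a ~30k-parameter net needs a far larger step
than the 1e-4 used with large pretrained encoders; 1e-4 remains the
config default for the full-scale recipe), cosine annealing to zero,
batch size 8. Config enums accept
`resnet50`/`efficientnet_b6` encoders and the `deeplabv3plus`
architecture as placeholders for GPU-scale runs; selecting them raises
`NotImplementedError` in this build.

The multi-label head trains with focal loss (alpha = 0.25, gamma = 2,
the standard defaults; both configurable). At gamma = 0, alpha = 1 the
implementation reduces exactly to binary cross-entropy, which is
tested to 1e-9. The binary filter trains with cross-entropy.

Augmentation (off by default in the desk-scale experiments, available
for all training entry points) applies, each with probability 0.5,
horizontal/vertical flips, rotation within +-45 degrees, zoom 80-120%,
translation within +-20% of the side, and shear 0-10%, jointly to
image and mask with nearest-neighbour mask warping.

## Phantom generator

The synthetic module draws stylized axial head slices: a bright
elliptical skull ring (intensity 0.95), mid-gray parenchyma (0.35), a
darker central ventricle (0.18), background 0.02, all in [0, 1] (no
Hounsfield modelling). Each non-empty slice receives 1-3 lesions
(probabilities 0.6/0.3/0.1) whose geometry encodes the subtype the way
the subtypes present on CT:

* EDH — thick biconvex lens against the inner skull (elliptic
  thickness profile, max 7-12% of the side);
* SDH — thin wide crescent hugging the inner skull (max 2.8-4.2%);
* IPH — compact elliptical blob inside the parenchyma;
* IVH — blob confined to the ventricle (dark surround);
* SAH — one or two thin curvilinear arcs at mid-radius.

Lesion pixels sit `lesion_intensity_contrast` (default 0.35) above the
tissue they replace, before Gaussian noise (default sd 0.05); masks are
exact by construction and subtype-coded 1-5. Subtype is therefore
inferable from shape and local context alone — thickness separates
EDH from SDH, skull adjacency separates both from IPH, the dark
surround marks IVH, thin non-mural arcs mark SAH — which is exactly
the signal the fusion classifier needs. Pixel spacing scales as
230.4 mm / side so the physical head size is resolution-independent;
slice thickness is 5 mm.

What the phantoms do **not** emulate: anatomy (gyri, ventricles beyond
one ellipse, bone inhomogeneity), partial-volume effects, scanner
artifacts, inter-patient variability of tissue attenuation, or 3-D
lesion continuity across slices. Passing tests therefore demonstrate
that the pipeline's machinery is correct and learns shape/position
signal at desk scale — not clinical-grade performance on real CT.

## Synthetic cohorts

The cohort generator draws patients meeting the moderate-to-severe TBI
inclusion window (GCS 3-12, age 18-80). Marginals qualitatively mirror
a real msTBI cohort: ln-age ~ N(ln 57.5, 0.18) truncated to [18, 80],
GCS mildly skewed toward low scores (median ~7), pupil reactivity
50/17/33% (both/one/none), CT findings and subtype prevalences at
their observed rates, hematoma volume lognormal (median 15 mL).
Outcomes are Bernoulli draws from two stated logistic models —
scheme A (death) and scheme B (death or coma; operationalized here
simply as a second coefficient set with a stronger GCS effect and a
higher-prevalence intercept, since the clinical definition of coma is
not modelled). Intercepts are set so scheme A prevalence is ~30% and
scheme B ~46%. Coefficients are expressed in the same units as the
outcome model's design matrix (ln-age, i.e. Box-Cox at lambda = 0; raw
GCS; volume per mL), and the true linear predictor is stored per row,
which makes full-likelihood coefficient recovery and Wald-interval
coverage directly testable.

## Outcome models

Four nested feature sets: CRASH-BASIC (Box-Cox age, GCS, two pupil
dummies with both-reactive reference, major extracranial injury);
CRASH-CT adds petechiae, effaced basal cisterns, SAH, midline shift
and non-evacuated hematoma (the negation of the evacuated flag);
+Volumes adds volume_ml; +Volumes+Subtypes adds the five indicators.
Models are refit on the cohort at hand: unpenalized logistic regression
(scikit-learn LBFGS for cross-validation; statsmodels for coefficient
inference) or a random forest (500 trees, sqrt(p) features per split,
unlimited depth). Cross-validation is stratified 5-fold — plain
k-fold risks single-class folds at n~150 — with accuracy, precision,
recall, F1 at threshold 0.5 and ROC AUC per fold. Single-class folds
are skipped with a warning; if all folds are degenerate the run errors.

Diagnostics: the Box-Cox exponent is chosen by profile maximum
likelihood on a grid over [-3, 3] in steps of 0.01 (scipy's
unconstrained MLE serves as an independent oracle in the tests); it is
fitted on the full cohort before CV for simplicity — a small leakage
that only affects one monotone transform — with a fixed-lambda mode
available. The Box-Tidwell test augments the logistic model with
x*ln(x) and reports that term's Wald p-value; simulation tests check
its type-I error and its power against a log-linear truth. Random
forest feature importances are mean decrease in impurity, averaged
over folds and normalized to sum 1.

## Experiment sizes and numerical choices

The reference experiments (`hemocascade.experiments`, re-run by
`scripts/acceptance.py`) use: 200 training / 50 held-out slices at
64x64 for the filter (20 epochs) and the segmentation cascade (30
epochs per stage); 300 training / 60 held-out fusion inputs, 30
epochs, averaged over 3 seeds; 2000-patient cohorts for the nested CV
comparison; 200 replicates at n = 2000 for the Box-Tidwell error
rates; 20 seeds at n = 5000 for coverage. These sizes were chosen so
the full suite runs on a single CPU in minutes while leaving each
comparison comfortably powered.

Other conventions: boxes are row-major, 0-based, half-open; Dice/IoU
are defined as 1.0 when both masks are empty (predicting "no
hemorrhage" on a clean slice is correct); per-subtype segmentation
scores attribute a slice's binary score to every subtype present in
its ground truth; scan-level labels are the logical OR of slice
labels; micro-AUC is reported as undefined (None/null) when the pooled
truths are single-class; max-pool gradient ties break to the first
maximum; NIfTI is the canonical series format with spacing carried in
the header, PNG directories need a JSON sidecar.

## Known limitations

* The tiny backbones are deliberately small; they saturate on phantom
  contrast but would underfit real CT. The full-scale encoders are
  config placeholders only.
* The voting rule between the two stages is a design choice (mean,
  union, intersection); no claim is made that it matches any
  particular published fusion scheme beyond reducing to agreement.
* Binary segmentation with subtype semantics carried by the classifier
  is one reading of a "multi-class segmenter"; subtype-coded masks are
  supported in the I/O layer but the cascade trains and predicts
  binary masks.
* Box-Cox on the full cohort before CV leaks a single scalar across
  folds; per-fold refitting is available but not the default.
* The phantom and cohort generators define the only evaluation
  conditions; no real-data performance is implied.
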