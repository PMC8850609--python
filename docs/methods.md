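# Methods

`thermoprick` implements an automated reader for skin prick tests (SPT)
from paired visible-spectrum and long-wave-infrared (thermal) forearm
images taken before and ~15 minutes after allergen application.  This
note documents the models, the synthetic benchmark, the numerical choices
and the limits of what the tests demonstrate.

## Problem and pipeline

Eight allergen application fields are drawn on each forearm as highlighter
marks in a 2x4 grid — seven circles and one square (the histamine positive
control); one circle is a diluent-only negative control.  A positive
reaction produces a wheal (visible) and a localized hyperthermic spot
(thermal).  The pipeline:

1. **Segmentation** — a U-Net predicts a per-pixel marker-probability map
   from the visible image; connected components of the thresholded map are
   filtered by bounding-box size and aspect ratio; a grid-completion
   heuristic arranges survivors into the 2x4 grid and synthesises missing
   positions.
2. **Registration** — the pre-application thermal image is aligned to the
   post-application one using the eight marker centers (homography or a
   rigid "two fitted lines" transform) and subtracted, giving a *delta*
   thermal image that ideally contains only reaction-induced warming.
3. **Classification** — per site, a 300x300 visible ROI (post series) and
   the matching delta-image crop, plus four patient attributes (sex, age,
   weight, body temperature), feed a convolutional network that outputs a
   reaction probability.
4. **Evaluation** — patient-grouped k-fold / leave-one-patient-out CV;
   ROC AUC, average precision, and accuracy at the F1-optimal threshold on
   the pooled test scores.

## Coordinate and data conventions

All code uses 0-based `(row, col)` pixel coordinates, origin top-left.
Bounding boxes are half-open `(min_row, min_col, height, width)`.
Transforms are 3x3 homogeneous matrices acting on `[row, col, 1]`.
Visible images are float in [0, 1] (8-bit RGB on disk); thermal images are
degrees Celsius (float32 single-channel TIFF on disk, CSV accepted for
fixtures).  The native acquisition frame is 1024x770 (width x height);
the package's default working scale is the half-native 512x385 frame the
U-Net trains at.

## Segmentation

**Ground-truth masks.** Each annotated site contributes a filled disc
centred on the injection point with radius equal to the distance to the
marked highlighter point.  Square (histamine) markers are rendered as
circles too — a deliberate simplification; the contour filter and the
300x300 ROI margin absorb the shape error.

**U-Net.** Classic encoder-decoder with skip connections: double-conv
blocks (3x3, same padding), 2x2 max pooling, x2 nearest upsampling + 3x3
convolution on the expanding path, a final 1x1 convolution, sigmoid via
the loss.  Batch normalisation is enabled by default for optimisation
stability on small batches.  Inputs are reflect-padded to a multiple of
`2**depth`, outputs cropped back, so odd sizes (385 rows) need no special
casing.  Training: Adam at 0.001 (its conventional default rate), binary
cross-entropy, 30 epochs, batch 2, inputs normalised to [0, 1].  The
full-width network (`base_channels=64, depth=4`) is the default
constructor; the benchmark suite trains a narrow variant
(`base_channels=4, depth=3`) whose receptive field (~50 px) still covers a
marker disc — marker segmentation is a high-contrast task and does not
need the classic capacity.

**Contour filtering.** Candidate components must have bounding-box sides
inside [54, 114] px at native scale (observed marker boxes: mean 85,
min 60, max 104, widened ~10%) and aspect ratio in [0.6, 1.67].  The side
range rescales proportionally when filtering at other resolutions.

**Grid completion.** Detected segments are split into two lines at the
midpoint of the row-coordinate range; the grid pitch is the minimal
displacement between consecutive positioned segments; grid positions are
indexed from the right (position 0 = rightmost).  Two choices were
genuinely open and are made as follows:

* *Anchoring.* Positions are assigned from the **globally** rightmost
  detected marker (projected on the marker cloud's principal axis), not
  per line: with per-line anchoring, dropping a line's own rightmost
  marker (a quarter of single-dropout cases) silently shifts that whole
  line by one pitch.  A shared anchor survives any dropout pattern except
  the simultaneous loss of both rightmost markers.
* *Filling.* Missing positions come from a least-squares fit of
  `center ~ a_line + position * v` with the pitch vector `v` pooled across
  both lines — a line that keeps only two jittered markers is a poor
  extrapolation basis on its own.

Fewer than 4 segments, or all segments in one line, raise an
incomplete-grid error; the pipeline then falls back to the manual
annotations and logs the image.

## Registration

**Correspondences** are formed by equal grid index (never nearest
neighbour — the forearm moves between series).

**Homography**: normalised-DLT least squares over all eight pairs (scikit-
image's `ProjectiveTransform`), no robust reweighting — outliers are
handled upstream by the contour filter and grid completion.  The residual
reprojection RMS is reported alongside.

**Rigid two-lines method**: a line is fitted through each eight-marker
set; the rotation is the angle between the lines, and the translation
carries the pre-set centroid (which lies on its fitted line) onto the
post-set centroid, so the transformed pre line coincides with the post
line exactly.  The line fit minimises *orthogonal* distance (principal
axis / total least squares): ordinary row-on-col regression is not
rotation-equivariant when the markers span two grid rows — its slope is
attenuated by roughly the ratio of perpendicular to in-line variance,
which at a 5 degree pose change costs about a degree of rotation — while
the principal axis rotates exactly with the point set and handles
vertical lines with no special casing.

**Warping and delta.** The pre thermal image is inverse-mapped through
the estimated transform with bilinear interpolation
(`scipy.ndimage.map_coordinates`); output pixels without source support
are zeroed and excluded via a validity mask.  The delta is
`post - aligned pre` (warming positive) on the valid region, 0 elsewhere,
so downstream crops need no special casing.

## Classification

**Samples.** The visible ROI comes from the **post**-series visible image
(wheals only exist after application); the delta ROI is cut at the same
coordinates — the modalities are pixel-correlated by construction.
Attributes are sex ({0,1}), age, weight, body temperature; height is
recorded in interviews but not used by the classifier.

**Normalisation.** Image channels are standardised by per-channel
mean/std; attributes are min-max rescaled to [0, 1] without clipping
(test values outside the training range may leave [0, 1]).  Statistics
are fitted on the training patients of each fold only; the stats object
records the contributing patient ids and the CV driver asserts that no
test patient appears in them.  An attribute that happens to be constant
in a (very small) training fold has its range widened to 1 so that it
maps to a constant 0 instead of dividing by zero; a zero-variance image
channel is an error.

**Paired augmentation.** Horizontal/vertical flips, rotation up to
45 degrees, translation up to 4 px, zoom up to 1.3, each applied
independently with probability 0.5 and parameters drawn uniformly.  The
realised transform chain is composed into a single affine matrix and
applied identically to the visible and delta ROIs (bilinear, zero fill —
zero is the channel mean after normalisation).  Fresh draws every epoch;
no augmentation at inference.

**Network.** The trunk follows the fixed channel plan
(32P, 64P, 64, 128, 128P, 256, 256P, 256, 256P, 256, 256P; "P" = average
pool 3x3 stride 2, no padding): 3x3 same-padded convolutions, batch norm,
LeakyReLU(0.01).  For a 300x300 input the six pools leave a 3x3x256 map
(2304 features); the four attributes are concatenated after flattening,
then dense 64 -> LeakyReLU -> Dropout(0.5) -> dense 1.  The head is a
single logit with sigmoid and binary cross-entropy — mathematically
equivalent to a two-way softmax with cross-entropy, which resolves the
tension between "single output channel" and "softmax" descriptions of
such heads.  Optimiser: Adam with decoupled weight decay 1e-4 (biases and
norm parameters exempt), learning rate 0.001, fixed 80-epoch budget (the
stopping epoch is not critical for this architecture; no patience logic).
Batch size 32.

**Input-spectra variants.** `both` fuses visible + delta into a
4-channel tensor; `thermal_only` uses the 1-channel delta;
`visible_only` the 3-channel visible ROI.

**Desk-scale profile.** The benchmark suite uses 64x64 ROIs with a
truncated plan (16P, 32P, 32, 64P, 64P -> 3x3x64) and 6 epochs; the
synthetic task is high-SNR by design and saturates well before the full
budget.  The full-scale architecture remains the default.

## Numerical engine

No GPU tensor framework is used: the package ships a compact numpy
engine (`thermoprick.nn`) with hand-written backpropagation — Conv2d
(exact shifted-GEMM decomposition over the padded image's flattened
buffer), BatchNorm2d, LeakyReLU/ReLU, average/max pooling, nearest
upsampling, dense, inverted dropout, Adam/AdamW, stable
BCE-with-logits.  Everything is float32, single-threaded BLAS, and
bitwise reproducible for a fixed seed (all randomness flows through
`numpy.random.Generator`).  The convolution is verified against
`scipy.signal.correlate2d` and all layers against finite differences.

## Synthetic benchmark: what it emulates and what it does not

`thermoprick.synthetic` renders paired pre/post scenes with full ground
truth.  Defaults describe the half-native 385x512 frame:

| parameter | default | meaning |
|---|---|---|
| grid | 2x4, pitch 112 px, jitter ±4 px | application fields per forearm |
| marker radius | 19-24 px | detected boxes ~ 60-104 px at native scale |
| pose change | rotation ≤ 5°, translation ≤ 15 px | rigid, between series |
| hot spot | Gaussian, amplitude 1.5 °C, sigma 12 px | reaction warming |
| hive contrast | 0.25 (0.05 = "low contrast") | visible redness of a reaction |
| baseline | 33 °C + mild planar gradient | skin temperature |
| sensor noise | 0.05 °C per series | i.i.d. Gaussian |
| confounders | 10 hairs (cool, dark), 3 vessels (warm) | thin Gaussian-profile curves |
| prevalence | 0.3 | per allergen site; histamine forced 1, control forced 0 |

Reaction amplitude and spread are *benchmark* parameters chosen for a
clear signal-to-noise separation, not clinical claims — real reaction
temperature profiles are not published in quantitative form.  The scene
is re-rendered analytically at the transformed geometry for the post
series (discs, Gaussian bumps and line segments are closed under rigid
maps), so ground truth is exact to machine precision and, with zero
noise and zero pose change, the pre/post thermal images agree bitwise
outside the (4-sigma-truncated) hot spots.

Not modelled: photorealistic skin, perfusion physiology, the
displacement of reactions along blood vessels, non-rigid skin
deformation, camera calibration or thermal drift.  Consequently the
synthetic results demonstrate that the pipeline's machinery is correct
and learnable, not that clinical performance transfers: the reported
clinical-scale metrics of the reference study are not reproducible here
because that dataset is private.

Deliberate degenerate-case semantics: IoU of two empty masks is 1.0;
delta pixels without warp support are 0 with the mask retained; the
U-Net binarisation threshold is 0.5.

## Benchmark problem sizes

The shipped acceptance checks use: 100 synthetic cases for registration
recovery (pixel-quantisation marker noise, ±0.5 px per axis); 500 grids
with 1-2 dropped markers for grid completion (≥95% of centers within
10 px); 40 training + 10 held-out half-size images, 30 epochs, for the
narrow U-Net (median per-site disc IoU ≥ 0.8); a 40-patient cohort
(640 sites), 64x64 ROIs, patient-grouped 5-fold CV for classification
(thermal-only pooled AUC ≥ 0.95, and visible-only ≤ both when hives are
rendered at low contrast).  These sizes are the package's chosen desk
scale; the generators accept larger cohorts unchanged.

## Known limitations

* Grid completion cannot recover the simultaneous dropout of both
  rightmost markers (the anchor itself); those cases account for the few
  percent of unrecovered centers in the benchmark.
* The homography, with 8 degrees of freedom fitted to 8 points, absorbs
  roughly `noise_sd * sqrt(2)` of marker noise into its reprojection
  against ground truth; with sub-pixel detection noise this stays well
  under half a pixel, but it is the dominant registration error term.
* Threshold selection for accuracy happens on the pooled cross-validated
  scores (a nested variant is available via per-fold reports); pooled
  selection slightly flatters accuracy but matches the single reported
  threshold convention.
* Training the full-width U-Net or the full 300x300 classifier on CPU is
  possible but slow; the desk profiles exist for exactly that reason.
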