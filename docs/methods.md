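# Methods

## Model

A B-scan is partitioned into `C` equal-width columns, tied to the width of
the backbone's feature map (`C = W_z`). The model predicts a
`(1+C) × B` collection of probabilities per slice: row 0 is presence of each
of the `B` markers anywhere in the slice, rows `1..C` presence in each
column. Both kinds of output share one affine classifier applied to pooled
descriptors of the same feature map: the slice descriptor concatenates
average and maximum pooling over the whole map, each column descriptor
average and maximum pooling over that column. The average component
captures extended fluid, the maximum small high-contrast pockets; sharing
the classifier between the slice row and the columns is what lets purely
slice-level supervision calibrate column scores.

Assumptions: markers are laterally localized (a column either does or does
not contain fluid); the fovea's lateral position is known (default: scan
center); B-scans in a volume are parallel and evenly spaced; the retina is
flat enough that the ETDRS grid can be treated as concentric circles on the
en-face plane rather than draped over surface topology.

## Losses

Training sees only slice labels `y_0 ∈ {0,1}^B`. Three terms:

* `l1`: BCE on the slice row, summed over markers.
* `l2`: multiple-instance constraint. Absent marker: mean over columns of
  `−log(1−ŷ_c)` (every column pushed down). Present marker:
  `−log max_c ŷ_c` (at least one column pushed up). We compute log-of-max
  rather than max-of-log (identical by monotonicity, numerically safer);
  gradient ties at the max go to the lowest column index.
* `l3`: flip consistency. For the mirrored input `x'`, column `c` of `ŷ'`
  is compared with column `C−1−c` of `ŷ` through a symmetric Bernoulli KL
  divergence, summed over columns and markers. Interpreting the scalar KL
  as Bernoulli KL is the only reading that vanishes at equality for all
  probabilities.

The total is `l1 + l1' + l2 + l2' + l3` on the pair `(x, x')`. Ablation
configurations are restricted to the nested subsets {l1}, {l1,l2},
{l1,l2,l3}; other subsets are rejected because `l2` without `l1` leaves the
slice row untrained and `l3` without `l2` has a trivial constant-output
minimum.

Numerical choices: probabilities are clamped to `[1e-7, 1−1e-7]` before any
logarithm (the losses are unbounded at {0,1} and sigmoids saturate);
clamped entries receive no gradient; losses are summed over markers and
averaged over the batch. Loss arithmetic follows the input precision:
float32 in the training graph, float64 when called on plain float64 arrays
(which is how the oracle-agreement tests run).

## Ring geometry

A slice at signed distance `d` from the fovea intersects the disc of radius
`r` in the chord `|x − x_f| < sqrt(r² − d²)`. Ring `j` (annulus between
`r_{j−1}` and `r_j`, ring 1 being the central disc) therefore occupies 0, 1
or 2 half-open lateral stripes. `w_{c,j}` is the fraction of column `c`'s
width inside ring `j`'s stripes; a slice with `|d|` beyond the outermost
radius yields an all-zero matrix rather than an error (such slices exist in
real raster scans). Ring probability is `max_c w_{c,j}·ŷ_c`: the max-of-
weighted-probability form reproduces both limiting behaviours (a column
fully inside contributes its probability unchanged; a column outside
contributes nothing). The alternative reading — max first, weight after —
differs only for rings whose best column is partially outside; we fixed the
weighted-then-max form because it is continuous in the geometry.
Coordinates are measured in mm from the left edge; columns and stripes are
half-open `[a, b)`; rings with no overlapping column are flagged invalid
and carry NaN.

## Architecture and training

The feature extractor is a stack of 4×4, stride-2 convolution blocks with
per-channel instance normalization and ReLU. Two design points matter:

* **Mirror consistency.** Even kernels aligned with the stride make the
  architecture commute with horizontal flips (odd kernels with stride 2
  shift the flipped feature map by one pixel per level). On top of that,
  weights are initialized *mirror-paired*: channel `2i+1` is the horizontal
  mirror of channel `2i` (with input-channel pairs swapped in deeper
  layers) and the head ties its weights across each pair, so the network is
  exactly flip-equivariant at initialization. The flip-consistency loss
  then starts at zero and maintains the symmetry during training instead of
  spending capacity fighting an asymmetric initialization.
* **Normalization.** Instance normalization (per sample, per channel over
  space) keeps activations well-scaled for a from-scratch training run, is
  identical at train and test time, and commutes with flips.

Two named configurations ship: `conv1792` (stride 32, `D_z = 1792`,
512×512 input → 1792×16×16 map, descriptors of length 3584 — the feature
geometry of the published clinical model) and `tiny` (stride 16,
channels 24/48/64/64, `D_z = 64`, 128×128 input → 8 columns) for CPU-scale
experiments. Grayscale input is replicated to the extractor's channel
count; inputs are resized to the configured square size.

Training is two-stage: stage 1 optimises `l1` only (slice-level multilabel
classification); stage 2 fine-tunes everything with the full loss on
flipped pairs. Defaults follow the published recipe — batch 32, SGD with
momentum 0.9, base lr 5e-3 scaled by 0.99 per epoch, 10 fine-tuning
epochs; the pretraining stage length (default 3 epochs) and its learning
rate are configurable separately since the recipe leaves them open. All
randomness (init, shuffling) derives from one seed; two runs with the same
seed agree bit-for-bit on one CPU. A NaN loss aborts with the per-term
breakdown in the message.

## Synthetic data

The generator emulates the cues the method relies on, not OCT physics: a
curved, layered retina band (constant thickness, depth-weighted mean
reflectivity normalized per slice) over a dark floor with multiplicative
Gaussian speckle; the IRF-like marker as dark elliptic inclusions inside
the band (intensity scaled by 1−0.65); the SRF-like marker as bright
elongated pockets hugging the lower band boundary, laterally concentrated
near the scan center (as SRF rarely reaches the outer rings), present in
≈5 % of slices to reproduce the rare-marker regime. Volumes share 3-D
pockets across consecutive slices so en-face ground truth is spatially
coherent. Slice labels, pixel masks and column masks (at-least-one-pixel
rule) are derived from the rasterized footprints, so label consistency is
exact by construction.

What it does not emulate: real speckle statistics, vitreous/choroid
texture, retinal layer anatomy, pathology other than fluid, motion
artifacts, vendor-specific intensity profiles. Passing the synthetic
benchmark therefore shows the *method* (pooling head, losses, geometry)
works when the marker is visible as a local intensity anomaly; it does not
certify clinical performance.

Background variability is deliberately kept below the fluid signal: a
linear probe on mean column intensity must separate positive from negative
columns (AUC > 0.95), which guarantees localization failures in training
experiments indicate method bugs, not an unsolvable task. The residual
probe error comes from columns a blob overlaps by only a few pixels — the
at-least-one-pixel column rule makes them positive while barely moving any
intensity statistic; this same tail bounds achievable column AUC.

## Benchmark conditions

The synthetic benchmark trains the `tiny` backbone from scratch: 24
training and 12 test volumes of 8 slices (192/96 slices, disjoint generator
seeds), batch 8, pretraining 12 epochs at lr 7.5e-3, fine-tuning 10 epochs
at lr 2e-3, three seeds. The rates are higher than the clinical recipe
because no pretrained initialization exists and the dataset is ~100×
smaller; a gentle pretraining rate matters more than a long schedule —
stage 1 sets the feature quality that the weakly supervised stage can only
partially repair. The stage-1 model is shared across the three ablation
fine-tunes of a seed (stage 1 does not depend on the ablation subset).
Problem sizes were chosen so the full nine-model suite runs in minutes on
one CPU.

The ablation comparison uses the column AUC averaged over markers: the
column constraint's benefit concentrates on the rare marker (with
slice-level BCE alone the rare marker's columns are essentially
uncalibrated), while the common marker is often already well localized
through the shared head. When a test split contains no positive column for
the rare marker its AUC is undefined and that seed contributes the defined
markers only.

## Known limitations

* Column granularity is bounded by the feature-map width; predictions
  cannot resolve sub-column structure.
* The rare-marker (SRF-like) column AUC is essentially undetermined at
  benchmark scale (a handful of positive slices); only the common marker's
  localization is asserted.
* The en-face area uses a hard 0.5 threshold on probabilities; integrating
  probabilities instead would change absolute areas (the threshold is a
  parameter of `enface_area_mm2`).
* Fitted models are specific to the configured image size and column
  count; there is no cross-resolution transfer.
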