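# Methods

This note records the modelling choices behind `iifseg`: what each stage
assumes, which parameters matter, what the synthetic substrates do and do
not emulate, and where the design was genuinely open.

## Pipeline model

Both substrates share one architecture: segment the tissue at a reduced
working resolution, derive from the segmentation the small region where the
diagnostic signal can occur, classify only that region, and convert the
resulting brightness scores into endpoint titers across a dilution series.

### Segmentation

The segmenter is a per-pixel classifier: each pixel is described by a
multiscale feature vector — Gaussian pyramid (σ = 1…16 px), difference of
Gaussians, gradient magnitudes, local standard deviation, a wide-context
mean (σ = 24 px), structure-tensor coherence at two scales, and min/max of
the blurred intensity sampled 12 px away in eight directions — and mapped
to class probabilities by a small ReLU perceptron (default two hidden
layers, 32 and 16 units). Two feature groups carry identifiable roles: the
coherence features separate fibrous tissue (dermis, muscle layers) from
cellular tissue (epidermis, epithelium) in a rotation-invariant way, and
the directional-surround minimum distinguishes a dark gap *between* tissue
(the interspace of the split) from dark background outside it, which purely
local features cannot do.

A purely local classifier produces salt-and-pepper label noise that a
convolutional decoder would smooth away; the equivalent regularization here
is a Gaussian blur (σ = 1.5 px at working scale) of the per-class
probability maps before the argmax. The probability/argmax contract of the
result is unaffected.

Losses follow the substrate: generalized Dice for split skin (the
interspace and the thin boundary regions are heavily outnumbered),
categorical cross-entropy for esophagus. The generalized Dice loss uses
inverse-squared-volume class weights `w_l = 1/max(Σ r_l, 1)²`; the clamp
keeps classes absent from a batch from dividing by zero. Note an algebraic
subtlety: GDL equals `1 − 2q` independently of class volumes only when all
classes share the same overlap ratio `q = I_l/S_l`; with heterogeneous
per-class quality, changing one class's volume shifts the weighted mixture
slightly (order 10⁻²–10⁻³ per decade of volume). The robustness the loss
buys is that no class's contribution scales with its area.

Training: Adam (β = 0.9/0.999), learning rate 10⁻², 10–12 epochs over
class-stratified pixel samples (≈3,000 px/image), with flip and full-angle
rotation augmentation applied to image and mask together (zoom optional,
0.9–1.1). Everything is plain NumPy and byte-reproducible for a fixed seed;
head weights start at zero, so an untrained model predicts the uniform
distribution.

### Split-skin attention and patches

Attention lines are the literal dilation-overlap set equations with a
Euclidean disc of 3 px diameter — the radius-1.5 disc centred on the grid,
i.e. the full 3×3 neighbourhood, since a radius-1.0 disc would exclude
diagonals and no sub-pixel convention is available. The equations are
evaluated exactly; all cleaning happens upstream in the segmentation.

Patch centres are drawn on the **skeleton** (medial axis) of the attention
line: the line is a few pixels thick and its width would otherwise turn
into lateral centre jitter at the 4× classification scale. Poisson-disc
sampling is greedy dart throwing in seeded random order; the default radius
is the estimated line length (skeleton pixel count × scale) divided by
n+1 = 41, clamped to [8, 64] px. Short lines yield fewer patches and are
padded with empty patches to the fixed count of 40 — padding patches are
scored like any other and learn the 'background' label, so they drop out of
the aggregation. Patches crossing the image border are shifted inward; the
minimum-distance guarantee applies to the sampled centres before that
shift.

The patch net sees 16 summary features of the 64×64 patch (quantiles,
row/column profile maxima, centre-vs-outer contrast, gradient statistics,
peak offset from centre) and has two heads: a 4-class softmax trained with
cross-entropy and a linear brightness head trained with MSE, weighted
equally; brightness targets exist only for tissue patches. Training patches
come from ground-truth geometry with three deliberate label choices:

* stretches where roof and floor remain attached are taught as 'unclear' —
  either binding produces the same junction fluorescence there, exactly the
  ambiguity readers resolve by looking at the open cleft;
* centres are jittered ±6 px to match the localization error of attention
  lines derived from quarter-resolution segmentations;
* patches displaced 10–24 px off the line are also 'unclear': they may show
  staining, but off-centre staining does not identify the sampled side.

Aggregation implements the mean-of-argmax-probability formula; `f(x_i)` is
read as the probability of the patch's argmax label, which keeps both sums
in [0, 1]. Empty P or N contributes 0, so no informative patch gives
y = 0.5. The decision threshold on y defaults to 0.5 (ties positive) but
is an operating point, and the benchmarks calibrate it the way a
laboratory would: negative images concentrate near y ≈ 0.05 (every
informative patch votes negative) while positive images mix positive and
negative votes and land near y ≈ 0.5, so each side's threshold is chosen
by grid search on the labeled *training* images (ties resolved toward
0.5) and stored with the patch model. A side with no positive patch is
reported negative regardless of y, since there is nothing to titer. Brightness is the mean over min(3, |P|) top
positives, undefined at |P| = 0. One property worth knowing: with
heterogeneous confidences the mean-based y is not globally monotone under
converting a single negative vote to positive (removing a low-confidence
element can lower the positive mean); monotonicity holds at uniform
confidence.

### Esophagus classification and intensity

The classifier is dual-input by construction: its features pool intensities
inside the predicted BMZ mask, in a ring extending 12 px to either side
(the adjacent epithelium), and globally; a connected-component statistic on
the bright ring pixels separates the one-piece intercellular network from
fragmented nuclear-speckle confounders. Two sigmoid heads trained with
binary cross-entropy give independent per-pattern probabilities, so
dual-positive sera remain representable; 'negative' is the absence of
calls at the 0.5 thresholds. Segmentation maps are produced on the fly by
the trained segmenter during classifier training, so the classifier learns
against realistic mask noise.

The desmosome region is the BMZ mask dilated band_px (default 20 at
working scale) times with the unit disc, intersected with the epithelium
class — iterated binary dilation being the thresholded box-convolution. The
pattern intensity is the q = 0.95 quantile of pixel intensities in the
pattern's region, mapped to the [1, 5] score scale by piecewise-linear
calibration knots. The default knots are the identity-like map raw 0 → 1,
raw 1 → 5; the benchmarks use knots anchored at the substrate's
autofluorescence baseline and baseline-plus-full-reaction amplitude, which
is how a laboratory would calibrate against reference sera.

### Titer estimation

The canonical dilution series is 10, 32, 100, 320, 1000, 3200, 10000,
extended by the alternating ×3.2/×3.125 pattern. Scores are rounded to the
nearest integer (half up) before the additive rule d_{k+s−1}. For a series,
the lowest-dilution negative image caps the titer: the estimate comes from
the highest-dilution positive image below the first negative and is clamped
below the negative's dilution; without a negative image the
highest-dilution image is used as in the single-image case; an all-negative
series is negative without titer. The cap reading of the multi-image rule
is one of two defensible interpretations of the stated procedure and is
asserted only as this package's behaviour.

## Synthetic substrates

The generator renders what the pipeline needs to be *possible and
falsifiable*, not photorealism:

* split skin: a tissue band with a smooth random cleft, an attached
  fraction (default 0.3) where no interspace opens, and a clear minimum
  cleft opening (2.5 % of image height) where it does — real salt-split
  substrates cleave visibly within the lamina lucida, and without a floor
  width the two sides' fluorescence would be geometrically inseparable;
* esophagus: seven stacked layers with wavy boundaries, per-layer
  autofluorescence baselines, a 2–3 px BMZ line, and a Voronoi-ridge
  intercellular mesh in the epithelium;
* reactions as additive bands (amplitude 0.55 × brightness β ∈ (0, 1]),
  the score scale defined as s = 1 + 4β;
* confounders: nuclear speckles inside epidermis/epithelium and diffuse
  unspecific glow, both always labeled negative for the disease patterns;
* noise: one knob (`noise_sd`, default 0.02) scales additive Gaussian
  noise, tissue texture (2×) and a multiplicative shading field (4×), so
  `noise_sd = 0` renders piecewise-constant scenes for analytic checks.
  Dermal/muscle textures are anisotropic (fibrous), epidermal/epithelial
  textures isotropic — a real histological contrast that also carries the
  learnable roof/floor signal.

Dilution series scale brightness linearly to zero at the endpoint index;
for endpoints within the five-score range this makes the score fall exactly
one point per dilution step, consistent with the additive titer rule.

What the generator does **not** model: real tissue morphology and staining
texture, IgA vs IgG conjugates, multi-channel counterstains, sectioning
artifacts, focus variation, and endomysial patterns. Passing the synthetic
end-to-end benchmarks therefore demonstrates that the pipeline's machinery
— segmentation-guided attention, patch aggregation, intensity-to-titer
arithmetic — recovers known ground truth under controlled difficulty; it
does not certify performance on patient material.

## Problem sizes and numerics

Benchmarks and tests run on a 512×512 canvas with segmentation at 128 px
(split skin) / 256 px (esophagus) and classification rasters at 512 px,
preserving the 4× segmentation-to-classification ratio of the full-scale
configuration (512² → 2,048²), which remains the config default. The
study-scale benchmark uses 100 training and 40 held-out images per
substrate (40 % negative, 30 % per pattern, brightness uniform in
[0.2, 1.0], 20 % confounder rate) and reaches ≥ 0.9 pattern-call accuracy
on both substrates; misses concentrate in low-brightness borderline cases,
the same failure mode the original readers report. Quantiles use linear
interpolation of order statistics; masks resample nearest-neighbour,
intensities bilinearly; intensities are clipped to [0, 1] after every
compositing step; all randomness flows from explicit integer seeds through
PCG64 streams.

## Known limitations

* The trainable components are feature-based perceptrons, sized for CPU
  determinism, not convolutional networks; on real micrographs their
  engineered features would need revisiting.
* Attention-line quality is bounded by segmentation quality; spurious line
  fragments from residual label noise are handled statistically (patches
  vote 'unclear'/'background') rather than removed geometrically.
* Score calibration for esophagus intensity is substrate-relative; applying
  the pipeline to a new imaging setup requires re-anchoring the knots.
* The multi-image titer rule's cap interpretation and the exact quantile
  (0.95) are package choices where the procedure's source left latitude.
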