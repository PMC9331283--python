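# Methods and design notes

This note records the models implemented by the package, the conventions
chosen where the feature definitions leave room, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.

## Acoustic model of prosodic flatness

**Framing.** Speech is treated as quasi-stationary within a frame.
Defaults are 25 ms frames with a 10 ms hop (standard speech analysis
framing); both are configurable. Trailing samples shorter than one frame
are dropped.

**Intensity convention.** Per-sample intensity is *squared amplitude*
(acoustic power) by default; absolute amplitude is selectable. PIVD
values depend on this choice, so feature tables produced under different
conventions are not comparable.

**PIVD denominator.** With `num_f` frames the first-order difference
sequence has `num_f − 1` elements and the squared deviations are divided
by `num_f − 1` — i.e. the population SD of the difference sequence. The
statistic is translation-invariant in the intensity track and scales
linearly with it.

**MFCC recipe.** Hamming window per frame, FFT length equal to the frame
length, power spectrum, 12 triangular mel filters spanning 0 Hz–Nyquist
(HTK mel scale), log with a 1e-10 floor, orthonormal DCT-II. All 12
cepstral coefficients are kept, including c0: with 12 filters the DCT
yields exactly 12 coefficients, and dropping c0 would leave 11. No
pre-emphasis by default.

**Second-order delta cepstrum.** The five-frame kernel
`(−2, −1, 0, 1, 2) / 3` is applied per coefficient column. The
denominator is 3 *by definition of this feature set* — not the
conventional regression normalizer `Σ 2n² = 10`. Boundary frames
replicate the first/last rows before the kernel is applied. The kernel
weights sum to zero, so any frame-constant matrix maps to zero exactly.

**AFVC.** The coefficient of variation is computed as the *population*
SD of the 24 column means (divide by 24 under the root) over the absolute
value of their mean. A near-zero mean (|mean| < 1e-9) makes the ratio
meaningless; the package raises a degenerate-input error rather than
clamping silently. AFVC is invariant under positive scaling of the
24-element sequence.

**Pitch baseline.** A plain short-time autocorrelation tracker: 40 ms
frames, 10 ms hop, search range 60–400 Hz, voicing threshold 0.3 on the
normalized autocorrelation peak, parabolic lag refinement. Statistics
are taken over voiced frames only.

## Head-movement features

Image axes follow the standard convention: x grows rightward (the
repeated-reading dimension Rr), y grows downward (the unconscious-movement
dimension Um). The head trajectory is the mean frame difference of the
17 jaw-contour landmarks, which makes it exactly equivariant under global
translation of the face.

**Rotation events.** The binarized Rr trajectory uses a symmetric dead
band (default 0.2 px) with state carry-over; leading dead-band frames take
the first decisive direction, and an entirely indecisive trajectory is
treated as a constant rightward state. Runs shorter than the minimum run
length (default 3 frames) are absorbed into the preceding run to suppress
landmark jitter. A *rotation* is a 1→0 transition of the filtered
sequence — the leftward return that ends a rightward reading sweep. This
makes a straight-through reading of `n_l` lines produce exactly `n_l`
rotations and hence RHR = 1; only re-reading pushes RHR above 1.

**MEA comparator.** Motion energy sums absolute gray-level frame
differences above a noise threshold (default 10 gray levels on a 0–255
scale) inside a head region of interest (default: the jaw-contour
bounding box dilated by 20 %), normalized by ROI area and averaged over
frame pairs. It measures movement *amount* only; the package's tests
verify that on trajectory-structured synthetic cohorts it separates the
groups worse than RHR + UHD.

## Mouth-fluency representations

**MAR.** Mouth width is the distance between landmarks 52 and 58, mouth
length between 49 and 55 (1-based indexing). Frames with failed landmark
detection (NaN) are linearly interpolated from neighbours; leading and
trailing gaps replicate the nearest valid value. Coincident mouth
corners (zero length) raise an error naming the frame.

**Time-domain map.** Sequence values fill a `ceil(sqrt(L))`-sided square
row-major with zero padding; the red channel carries `round(200 · value)`
clipped to [0, 255] (round-half-up, so two values differing by ≥ 1/200
within the unclipped range always produce different pixels); green and
blue are zero. The square is nearest-neighbour resized to the backbone
input side (default 224), which preserves every element whenever the grid
is no larger than the output. The exact pixel layout is one of several
defensible geometries; row-major filling was chosen for simplicity and is
documented as an interpretation.

**3-D spectrogram.** The MAR sequence is cut into 3 s segments hopped
every 1 s (`floor((L − 3·fps)/fps) + 1` segments); each segment is
Hamming-windowed and transformed with a single FFT — no intra-segment
sub-windowing. Magnitudes are normalized by the recording's global
maximum and rendered as a fixed-viewpoint (elev 35°, azim −60°) 3-D
surface with a fixed perceptually-uniform colormap and no axis
decorations (the image is consumed by a convolutional network). The
rendering is deterministic for a given sequence and configuration.

## Transfer-learned RRF embedding

The backbone is pluggable. The default, `tiny-random`, is a small seeded
random-convolution network (two 3×3 conv + ReLU stages over a mean-pooled
56×56 input, global mean+max pooling, 32 features) whose filters are
drawn once from a fixed seed and never updated. Random frozen
convolutions are a standard lightweight feature extractor; the important
contracts — frozen convolutional parameters (checksum-identical before
and after head training), deterministic features, a trainable binary
head — are exactly those of a pretrained residual backbone, which can be
registered under `resnet101` by a user who has one.

The head is a 2-unit linear layer trained by seeded mini-batch SGD on
softmax cross-entropy with the published recipe: batch 10, 140 epochs,
learning rate 1e-4, no scheduling. Backbone features are standardized
with training-set statistics. RRF features are the *pre-softmax* logits
(richer scale information than probabilities; configurable), two per
image, concatenated time-map first.

Inside cross-validation the heads are retrained per fold on the training
rows only. Backbone features may be cached across folds because the
frozen convolutions are identical in every fold; the fold-specific parts
(feature standardization and head weights) never see test rows. A
global-training mode would be optimistic and is deliberately not the
default.

## Evaluation protocol

Stratified 10-fold CV repeated 5 times; metrics are computed per fold and
averaged over all repeats × folds. Folds group by subject by default:
with 4 segments per subject, splitting by segment lets a classifier
re-identify subjects rather than groups, which inflates every metric.
The per-segment mode exists behind a flag and is documented as
optimistic. SVM uses an RBF kernel with C = 1 on features standardized
by training-fold statistics, and its decision function provides ROC
scores; the random forest uses 500 trees and class probabilities.
Specificity is the true-negative rate over controls, sensitivity the
true-positive rate over patients; single-class ground truth raises rather
than returning a defined value.

## Synthetic cohort generator

The generator emulates the *claimed group differences*, not speech or
faces:

- audio is harmonic material (f0 = 200 Hz, 6 harmonics with geometric
  decay, optional broadband floor), with syllable-paced (5.5 Hz)
  sinusoid-plus-noise amplitude modulation and slow vibrato;
- landmarks are a fixed face template translated rigidly by a
  constructed head trajectory — one rightward sweep and leftward return
  per text line, Poisson-distributed extra re-read rotations, a
  deterministic vertical line step and Gaussian vertical jitter — with
  mouth landmarks oscillating at 4 Hz, interrupted by Poisson pauses.

Group blocks set the means of six knobs (amplitude-modulation depth,
vibrato depth, harmonic decay, extra rotations per line, vertical jitter
SD, pause rate); subjects draw log-normal values around their block's
means (σ = 0.35) and segments wobble around the subject values
(σ = 0.12). The default blocks give controls deeper loudness/pitch
modulation and a richer timbre (higher PIVD and AFVC) and patients more
re-reading, jitter and pauses (higher RHR and UHD, dysfluent MAR). The
carrier frequency of 200 Hz was chosen so that the 10 ms analysis hop
spans almost exactly two carrier periods, keeping the frame-boundary
ripple of the periodic carrier out of the intensity difference sequence;
with a misaligned carrier the ripple adds a depth-independent PIVD floor
that masks shallow modulation. Default effect sizes were chosen so that
the fused feature set lands in the high-80s-to-high-90s accuracy regime
while each single modality stays informative but imperfect; they are
calibration constants of the generator, not estimates of any clinical
effect size.

What passing tests on this material do show: the formulas are computed
correctly, the pipeline recovers injected parameters, group-difference
directions propagate through every stage, and fusion helps when both
modalities carry independent signal. What they do not show: anything
about effect sizes, classification accuracy, or robustness on real
clinical recordings — real speech and faces are vastly richer than this
generator.

**Zero-modulation edge case.** The "no modulation ⇒ PIVD ≈ 0" property
is exact only under period-aligned framing (frame and hop an integer
number of carrier periods) with the noise floor disabled, because the
per-frame mean intensity of a sampled periodic signal otherwise carries a
small boundary-phase ripple. The tests use frame 882 / hop 441 samples
at 44.1 kHz (4 and 2 periods of the 200 Hz carrier) for this case.

## Problem sizes

The default cohort is 2 × 20 subjects × 4 segments of 10 s (160
segments), mirroring the study design this pipeline targets; the
acceptance script evaluates it with the full 10 × 5 CV protocol in a few
minutes on one CPU. Sub-sampled cohorts (5–8 per group, 6 s segments,
22.05 kHz audio) are used for multi-cohort property checks such as
directional fidelity over 20 seeded cohorts; these sizes are the
package's choice of test conditions and are stated in the tests
themselves.

## Known limitations

- Landmark detection is out of scope: sequences come from files or a
  pluggable detector; their quality bounds every video feature.
- The rotation-event definition (leftward returns after run filtering)
  is one defensible reading of "number of head rotations"; counting
  rightward sweep starts instead shifts RHR by at most one event per
  segment boundary.
- The time-domain map geometry and the spectrogram rendering
  (viewpoint, colormap, no axes) are conventions; a CNN trained on one
  convention does not transfer to another.
- The tiny default backbone is far weaker than a pretrained deep
  residual network; RRF separability on real images would benefit from
  registering a pretrained backbone.
- AFVC is undefined for parameter sequences with near-zero mean; such
  segments should be excluded upstream rather than imputed.
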