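# Methods

This note documents the models, estimators and numerical choices behind
pcgpipe, in the order data flows through the pipeline. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

A heart-sound corpus is a set of mono WAV recordings, each labeled normal
or abnormal at the recording level (no heart-cycle annotations). Real
corpora of this kind are heterogeneous: recording lengths vary by an order
of magnitude and many recordings are dominated by handling, motion or
ambient noise. The pipeline's premise is that *removing unusable
recordings* is a cheaper and less destructive preprocessing step than
filtering or segmentation — filtering can delete the very spectral
structure a classifier needs, and segmentation is error-prone exactly on
the noisy recordings that cause trouble. The package therefore never
filters or segments; it curates, images, and classifies whole recordings.

## Per-recording statistics

**Duration** is `len(samples) / sample_rate`, computed at the native rate.

**SNR** must be estimated from a single unlabeled recording, which the
field has no canonical recipe for; the estimator here is package-defined
and all SNR semantics in the package (selection thresholds, generator
calibration) are defined against it. The waveform is framed (25 ms frames,
50 % hop, both config-exposed) and each frame's mean power computed.
Heart sounds are sparse high-energy transients over a quasi-stationary
floor, so frames are partitioned at the **median** frame power: strictly
above → signal-bearing, at/below → noise. Because signal frames contain
signal *plus* noise, the noise floor is subtracted before the ratio:

    SNR_dB = 10 · log10( (P_signal − P_noise) / P_noise )

Properties that follow:

* invariant under global amplitude scaling;
* sign-symmetric: clean recordings score positive, buried ones negative;
* a recording whose frames all carry identical power returns exactly 0 dB
  (degenerate contract — there is no contrast to measure);
* pure stationary noise scores *negative* (the between-halves gap of frame
  powers is small relative to the floor), with a rate-dependent floor of
  roughly −4 dB at 2000 Hz (25 ms frames): sampling spread of frame power
  bounds how negative the subtracted excess can appear. Requested
  generator SNRs below that floor saturate there.

The median split is parameter-free and deterministic; its known bias — at
most half the frames can be called "signal" — is immaterial for a
*ranking* statistic used with a fixed threshold.

## Kernel density estimation (duration-mode discovery)

The duration-selection rule needs the most common duration per class. This
is the mode of a 1-D Gaussian KDE

    f̂(x) = (1/(n·h)) Σᵢ K((Xᵢ − x)/h),   K(u) = exp(−u²/2)/√(2π)

fit per class to the duration column. The kernel is the *normalized*
Gaussian so that densities integrate to one — this makes the invariant
tests meaningful and leaves the argmax unchanged relative to any
unnormalized variant. Bandwidth defaults to Silverman's rule
`h = 0.9·min(sd, IQR/1.34)·n^(−1/5)` ("auto"), overridable; a zero-spread
sample falls back to h = 1 with a logged warning. The mode is a grid
argmax (default grid [0, max+5] s, step 0.5 s, ties to the smallest
value), matching the integer-second granularity at which duration modes
are meaningful.

## Gaussian mixture biclustering

The clustering selector fits a 2-component, diagonal-covariance Gaussian
mixture by expectation–maximization to the per-recording feature vectors
(duration, SNR), z-scored per dimension. EM is implemented directly:

* **E step** — responsibilities `t(i,k) = πₖN(xᵢ|μₖ,σₖ²) / Σⱼ πⱼN(xᵢ|μⱼ,σⱼ²)`,
  computed in log space with log-sum-exp normalization;
* **M step** — `πₖ = (1/n)Σᵢ t(i,k)`, `μₖ = Σᵢ t(i,k)xᵢ / Σᵢ t(i,k)`,
  `σₖ² = Σᵢ t(i,k)(xᵢ−μₖ)² / Σᵢ t(i,k)` with the *updated* mean inside the
  variance update.

Numerical guards: variances floored at 10⁻⁶ (in standardized units) to
prevent singular collapse; a component whose total responsibility
underflows (< 10⁻¹⁰) is re-seeded at a random data point with the global
variance. Initialization is k-means++-style seeding of the means from data
points, uniform weights, global variance — fully determined by the config
seed (default 42). Convergence: |Δ log-likelihood| < 10⁻⁶ or 200
iterations. The log-likelihood trace is recorded every iteration; EM
guarantees it is non-decreasing, which the test suite checks on every run.

"Densest cluster" = the component with more hard-assigned members
(argmax responsibility per recording); ties go to the larger mixture
weight. Classes are pooled for the fit (a `--per-class` variant would be
trivial but is not the default: both classes survive one pooled
clustering, which is how a curation step should behave).

## Selection rules

All selectors are pure functions of the stats table and manifest; they
re-read no audio, and each returns an exact partition (kept ∪ dropped =
input, disjoint) with the parameters actually used echoed in the result.

* **Duration**: keep a recording iff |duration − target(class)| ≤
  tolerance. Targets default to the per-class KDE modes; a fixed 20/35 s
  override exists. Tolerance defaults to ±2.5 s: exact equality on
  real-valued durations would keep almost nothing, and the window matches
  the granularity at which corpus durations cluster.
* **SNR**: keep iff SNR ≥ threshold, inclusive (0 dB default; `None`
  disables). Monotone: raising the threshold never keeps more.
* **GMM**: as above. Idempotence caveat: re-running the GMM selector on
  its own output refits on the reduced set and may split the surviving
  cluster; the duration and SNR rules are exactly idempotent.

## Spectrogram imaging

Recordings are resampled (polyphase) to the 44,100 Hz pipeline rate, then
framed with a 1024-sample FFT window, hop 512, Hann window, left-aligned
frames — so the frame count is exactly `1 + (n − 1024)//512`. The power
spectrum is projected through 128 unit-peak triangular filters spaced on
the HTK mel scale (2595·log10(1 + f/700)) from 0 to the Nyquist frequency,
and converted to dB relative to the grid maximum with a −80 dB floor.
Digital silence maps to a uniform −80 dB grid, and the dB grid is
invariant to amplitude scaling. An MFCC variant (DCT-II across the mel
axis) is provided for completeness; the imaging pipeline feeds the
classifier the log-mel grid, not the cepstrum.

Rendering maps dB over the fixed [−80, 0] range onto the "magma" colormap
and bilinearly resizes the grid to an exact 640×480 raster — time on x,
mel band on y, low frequencies at the bottom, no axes or margins, and
byte-deterministic for identical input. Hop, band count, window, floor and
colormap are artifact-defined (unstated upstream) and config-exposed.

No heart-cycle segmentation is performed anywhere; that is the point.

## Classifier

The network is backbone + head:

* **Backbone**: a stack of 3×3 same-convolution → ReLU → 2×2 max-pool
  blocks after an average-pool downsampling of the input raster.
  `tinycnn` (the tested, desk-scale configuration) downsamples 640×480 by
  8× and uses channels (32, 64, 128). The 17 classic ImageNet architecture
  names are registered as deeper/wider random-init stand-ins so that
  experiment configs naming them run end to end; no pretrained weights are
  bundled, and building one logs exactly that.
* **CoordConv row channel**: the backbone input carries a fourth channel
  holding the normalized row coordinate. Convolutions with global average
  pooling are translation-invariant, which would erase *which* mel band
  energy occupies — but band position is the discriminative axis of a
  spectrogram (a murmur band differs from a valve-sound band by position,
  not texture). The coordinate channel lets the first nonlinearity form
  band-gated feature detectors.
* **Head**: GlobalAveragePooling over the spatial feature map → dense 256
  → dense 128 → dense 64 (ReLU, He init) → BatchNormalization → dense 1
  with sigmoid. The output is P(abnormal); positive class = abnormal so
  sensitivity measures disease detection. Loss is binary cross-entropy
  (forced by the sigmoid output).

Training uses SGD with batch size 5, 30 epochs, learning rate 10⁻⁴, and
momentum 0.9 (momentum is unstated upstream; 0.9 is the field default and
is config-exposed). GAP features are standardized with training-set
mean/scale before the dense stack, and the final layer is
zero-initialized, so optimization starts as a linear probe on the head's
penultimate features and co-adapts from there — with 10⁻⁴ and a few
hundred updates, a large random initial logit would otherwise dominate
what training can move. By default the backbone is frozen (features are
then precomputed once); `freeze_backbone=False` backpropagates through the
conv stack as well. Every run is fully determined by the config seed:
initialization, shuffling, and therefore final parameters.

## Evaluation

Stratified 3-fold cross-validation (stratification keeps the minority
class in every fold; a class with fewer than k members is a validation
error). Per fold: train on 2/3, predict the held-out third at threshold
0.5, count the confusion matrix. Reported metrics: accuracy, sensitivity
tp/(tp+fn), precision tp/(tp+fp), specificity tn/(tn+fp), each averaged
over folds. A zero-denominator metric is reported as 0 with an
`undefined` flag, never NaN. Balanced accuracy (macro-averaged recall) is
reported alongside because recording-level benchmarks in this area
sometimes print a single symmetric "recall" column for both sensitivity
and specificity; carrying both readings makes reports comparable either
way.

## Synthetic corpus generator

The generator exists so that every stage is testable without downloads.
Each recording is a train of damped-sinusoid bursts at a sampled heart
rate (drawn N(70, 10²) bpm, clipped to 45–140): S1 (~40–60 Hz, 90 ms) at
each beat and S2 (~60–90 Hz, 70 ms) at 35 % of the cycle, with small
timing jitter. Abnormal recordings add a systolic murmur: 150–400 Hz
band-passed noise between S1 and S2 at `murmur_gain` relative amplitude
(default 1.0 — a prominent murmur, comparable in amplitude to the valve
sounds). Gaussian white noise is then added, its gain found by bisection
so that the package's own SNR estimator hits a per-recording target drawn
from the class's SNR distribution — SNR is *defined against the package
estimator*, which is what makes parameter-recovery and selection tests
well-posed. Durations are drawn from class-conditional Gaussians with
modes 20 s (normal) and 35 s (abnormal), sd 4 s, floored at 5 s; SNR
targets default to N(0 dB, 5² dB) for both classes; the native rate is
2000 Hz. A `synth_corrupt_recording` variant buries the heart sounds far
below the noise — its estimated SNR saturates at the estimator's
pure-noise floor (well below 0), so an SNR screen provably removes it.

What the generator emulates: class-conditional duration modes, SNR mass
centered at 0 dB, periodic S1/S2 structure, murmur-band abnormality, and
a corrupt-recording failure mode. What it does not: real murmur morphology
(crescendo/decrescendo shapes, diastolic murmurs, clicks), pathological
S1/S2 changes, sensor/channel effects, or inter-patient variability.
Passing tests therefore demonstrate that the *pipeline machinery* behaves
as specified under controlled conditions, not that any accuracy figure
transfers to clinical recordings.

A consequence of the estimator-calibrated noise model worth stating
explicitly: at an estimator-SNR of 0 dB the heart sounds are already
heavily buried (the murmur band sits only ~1 dB above the in-band noise),
so a corpus drawn at N(0, 5²) is *deliberately* half-unlearnable. That is
what makes SNR curation genuinely informative in the selection-vs-none
experiment. Tests that probe classifier capacity rather than curation
(the 40-train/20-test separability check, the murmur-gain monotonicity
check) therefore draw their fixture at curated quality, SNR ~ N(6, 2²) —
emulating a corpus *after* selection, which is what headline benchmark
rows train on — and the monotonicity fixture matches the two classes'
duration distributions so the murmur is the only class difference.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script to a
few minutes on one CPU: selection-vs-none runs 16+16 recordings per class
plus 6 corrupt injections per seed (20 seeds in the test, 5 in the
acceptance script); separability checks use 30–60 recordings; KDE/EM
oracles use 10²–2·10³ points. These sizes are the package's chosen
defaults for its own verification; all are parameters.

## Known limitations

* The SNR estimator's negative range is floored by frame-power sampling
  spread (≈ −4 dB at 2000 Hz native rate); recordings buried deeper than
  that are indistinguishable from one another (they are all dropped by
  the 0 dB screen, so the limitation does not affect curation outcomes).
* The 44,100 Hz pipeline rate spends most of the mel axis above the
  content of 2000 Hz-native corpora; heart-sound energy occupies the
  bottom ~25 % of bands. The rate is kept for fidelity to the benchmark
  configuration and is configurable.
* Random-init backbones are feature extractors, not learned
  representations; registry names other than `tinycnn` exist for
  configuration compatibility, and their desk-scale results say nothing
  about their pretrained counterparts.
* GMM selection with M = 2 assumes one dominant clean cluster; corpora
  with several quality regimes would need a model-order choice the
  package deliberately does not make.
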