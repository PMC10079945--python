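# Methods

`spikeraster` converts 1D non-stationary biosignals into binary 2D pixel
images and classifies those images with a compact convolutional network.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not emulate.

## Spike simulation

Action potentials are modelled as a cosine carrier under a Gaussian
envelope:

    V(t) = A · cos(2π (t − τ_ph)/τ₁) · exp(−(2.3548 t / τ₂)²)

with amplitude `A` (signal units), carrier period `τ₁` (s), envelope width
`τ₂` (s) and phase offset `τ_ph` (s). The constant 2.3548 = 2√(2 ln 2) is
the Gaussian FWHM factor and is fixed, not a parameter. Templates are
sampled at `fs` on a support centered on the envelope peak; the default
support is 56 samples (2.8 ms at 20 kHz), equal to the window length so
that each window carries one spike.

The three default parameter sets (a positive biphasic, a negative-leading
triphasic, and a broad slow-carrier shape) were chosen once so the
templates are visibly distinct — pairwise normalized cross-correlation
stays below 0.9 at every lag (measured maximum ≈ 0.77). They are fully
configurable.

A recording superposes the three template classes on a zero baseline.
Spike peak times are drawn per class as a homogeneous Poisson process at
the mean firing rate (default 3.3 Hz per class over 200 s, ten recordings
per trial); a placement whose 56-sample support would overlap an already
placed spike of any class is rejected and redrawn, with a bounded retry
budget so pathological rates fail loudly instead of hanging. Every placed
spike is recorded as a ground-truth annotation (peak sample index, class),
so the pipeline never performs spike detection.

**SNR convention.** Gaussian white noise is added with

    σ = max_k max_t |template_k(t)| / snr,

i.e. `snr` is the peak template amplitude over the noise standard
deviation, a standard convention for extracellular data. The convention
is configurable in the sense that σ follows directly from the templates
and `snr`; note that under this definition larger `snr` means cleaner
signal, so the "favorable" end of the 0.5–2.0 sweep is 2.0. `snr = inf`
gives the exact zero-noise limit used by several tests.

## EEG-like binary epochs

`simulate_binary_epochs` produces pre-windowed rows in the common EEG
epoch CSV dialect (178 feature columns plus an integer label column).
Non-seizure rows are low-amplitude 1/f-shaped noise; seizure rows add
high-amplitude rhythmic spike-wave bursts (amplitude 120–250 units,
0.02–0.06 cycles/sample) over the same background. This emulates only the
gross amplitude/rhythm contrast that separates ictal from interictal
EEG — not real electrode physics, artifacts, or patient variability — so
results on it demonstrate the pipeline's mechanics, not clinical
performance. The ingestion path also accepts externally supplied files in
the same dialect, collapsing a five-class labeling to binary (label 1 →
seizure, labels 2–5 → non-seizure); such rows are already windows, so each
row is min–max rescaled on its own and segmentation is skipped.

## Preprocessing

The pipeline order is fixed: whole-recording L2 normalization
(y = x/‖x‖₂), then a whole-recording affine rescale onto [0, 1], then
windowing. Unit-norm scaling alone cannot place a signed signal in
[0, 1], hence the explicit min–max step; it is applied over the whole
recording rather than per window so relative amplitudes between windows
survive. Constant or non-finite inputs are rejected (the rescale is
undefined for them).

Spike windows (56 samples) are centered on each annotation; windows
truncated by the recording edge, or overlapping the support of a
different-class spike, are discarded. Noise windows are non-overlapping
56-sample stretches containing no part of any spike support. Noise
windows are then randomly subsampled (seeded) to at most
`cap_ratio × mean spike-class count` (default 1.18, matching the class
balance of the reference experiment) so the classifier is not biased
toward the majority class. The train/test split shuffles with a seed and
takes `floor(train_fraction × total)` training windows (default 0.30;
floor reproduces the reference split arithmetic, e.g. 27,371 → 8,211 +
19,160).

## Rasterization

Sample `i` of an n-sample window is placed at column `i·(d+1)` — `d`
empty "dummy" columns between real samples (default 20) make the joined
trace render as a smooth curve — and at row `round((1 − value)/r)` with
amplitude resolution `r` (default 0.0005 → 2,001 rows; row 0 is amplitude
1, image-style top-left origin; half-values round up). The image is
H×W = (1/r + 1) × ((n−1)(d+1) + 1); the defaults give 2,001 × 1,156 for a
56-sample window. Consecutive sample pixels are joined with Bresenham's
line algorithm: integer-only decision updates

    D₀ = 2Δb − Δa,   D ≥ 0 → diagonal step, D += 2Δb − 2Δa
                     D < 0 → axis step,     D += 2Δb

generalized to all octants by swapping axes when |Δb| > |Δa| and stepping
with the sign of each span. Ties (D = 0) resolve toward the diagonal
step. Each segment costs max(|Δa|, |Δb|) + 1 pixels — linear in its span —
and the chain deviates from the ideal line by at most half a pixel along
the minor axis (verified exhaustively for all offsets up to 50 against a
midpoint-rounding oracle). Reversing a segment's endpoints reverses the
pixel chain except exactly at half-pixel ties, where the tie rule selects
the other of the two equally close pixels.

Images are written as bilevel PNG with a JSON sidecar (label, source
window, raster config) and a per-batch manifest CSV; the round trip is
lossless.

## The classifier

A LeNet-style CNN sized by two checked formulas,

    conv:  out = floor((N + 2P − K)/S) + 1
    pool:  out = floor((N − K)/S) + 1,

with five 3×3 same-padded convolution (stride 1, ReLU) + 2×2 stride-2
max-pool stages, feature maps tapering 128→64→32→32→16, batch
normalization between the fourth convolution and its pool, a 512-unit
fully connected ReLU layer with dropout 0.5, and a softmax output (4-way
for the spike task, 2-way for the binary task). A 320×320 single-channel
input is the unique simple geometry for which five halvings leave 10×10
maps and the flatten is exactly 16·10·10 = 1,600. Training uses RMSprop
(ρ = 0.9, ε = 1e−8) on categorical cross-entropy, learning rate 0.001,
batch size 32, 20 epochs by default, with He initialization; all
randomness (init, shuffling, dropout) derives from one seed, so training
is bit-reproducible on a fixed platform. The network is implemented
directly on numpy (im2col convolutions through BLAS matmuls, float32),
and a probe forward pass cross-checks every tensor shape against the
formula chain.

Rasterized images are larger than the network input, so they are
downscaled by block max-pooling: the source grid is partitioned into
near-equal rectangular blocks (one per output pixel) and a lit pixel
anywhere in a block lights the output pixel. Interpolation-based resizing
would nearly erase a one-pixel-wide curve; block-max preserves it.
Upscaling is refused by design.

## Evaluation

From the k×k confusion matrix (rows true, columns predicted), per-class
one-vs-rest metrics on the percent scale: precision = 100·TP/(TP+FP),
recall = 100·TP/(TP+FN), F1 = 2PR/(P+R). F1 computed on the percent scale
is algebraically identical to the fraction-scale value. Overall accuracy
is 100·trace/total, which equals micro-averaged recall and reduces to
(TP+TN)/(TP+FP+TN+FN) for two classes. Metrics with an empty denominator
are reported as NaN with a warning rather than silently zeroed. Values
are kept at full precision and rounded half-up to two decimals only at
report time.

## Pipeline and reproducibility

`run_pipeline` executes simulate → normalize/rescale → segment/balance →
split → rasterize → resize → train → predict → evaluate, writing each
stage's artifacts (recordings, window CSVs, split manifest, images with
manifests, model checkpoint, training history, predictions, report). One
top-level seed derives a per-stage sub-seed by hashing the stage name
(SHA-256, reduced below 2³¹), so stages are independently re-runnable
through the CLI subcommands yet jointly reproducible: driving the stages
through their file interfaces reproduces the in-memory run exactly
(recordings serialize at full precision to keep the two paths
bit-identical).

## Scaled-down experiment

The full-scale experiment (ten 200 s recordings per SNR, 2,001×1,156
images, 20 epochs) is sized for a cluster. The package's headline run —
`spikeraster.pipeline.scaled_down_config`, also executed by
`scripts/acceptance.py` — keeps the recording conditions (20 kHz, 3.3 Hz
per class, 200 s, the default templates) but uses two recordings at the
favorable snr = 2.0 (≈1,300 windows per spike class), a coarser raster
(r = 0.005, d = 4 → 201×276 images) downscaled to a 64×64 input, thinner
feature maps (32, 16, 16, 16, 16), a 128-unit FC layer and 10 epochs.
On one CPU it completes in a few minutes and reaches ≥90% overall 4-class
test accuracy on the 70% held-out partition (92.9% at seed 1).

## Known limitations and open points

- The raster width arithmetic gives (n−1)(d+1)+1 = 1,156 columns for the
  default 56-sample window; reports elsewhere of 1,155 for the same
  geometry count the last column index rather than the column count. This
  package uses 1,156 throughout.
- The printed convolution-size formula circulating for this architecture
  family sometimes appears with `+K`; only `−K` reproduces the stated
  layer sizes, so that is what `conv_output_size` implements.
- Whether amplitude quantization should round or truncate is
  under-determined; this package rounds half-up and documents the rule in
  the image sidecar via the config.
- The simulator's Gaussian-noise model has no 1/f background, electrode
  drift, or overlapping spikes, so accuracy on it is an upper bound on
  real extracellular data.
- Larger `snr` here means cleaner signal; when comparing against results
  that sweep an undefined "SNR" whose accuracy *falls* as the ratio
  rises, consider that their ratio may be inverted (noise over signal).
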