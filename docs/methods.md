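# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic data can and cannot tell you about field
recordings.

## Signal model and derived streams

A recording is a uniformly sampled six-axis series: acceleration in g,
angular rate in deg/s, on a shared time grid with spacing 1/fs (jitter
tolerance 1e−9 s).  All analysis operates on four derived streams — the
Euclidean magnitudes Ā and Ḡ of the two sensors and their first
differences.  Magnitudes are orientation-free, which is why the generator
can fix gravity per bout without loss.

The rate-of-change streams are plain first differences on the per-sample
scale, *not* multiplied by fs.  The choice only rescales those features by a
constant per configuration, and a monotone rescale cannot change any tree
split or any reported metric; `per_second` scaling would carry the same
information.  Differencing shortens the stream by one sample, so a window of
n base samples contributes n−1 difference samples — no padding is invented.

Annotation intervals are half-open [start, end) and a sample at exactly an
interval start belongs to that interval.  Samples outside every interval are
unlabelled; windows never span them, because a gap is a boundary of unknown
behaviour.

## Windowing

Window length n = w × fs must be a whole (and, for exact 50 % overlap, even)
number of samples; all supported grid configurations (24–224 samples) are
even, and an odd n falls back to a floor(n/2) step.  Starts advance by n/2,
trailing partial windows are dropped.  A window with more than one label is
*mixed* and takes the predominant label; a tie goes to the label occurring
earliest in the window (deterministic and order-respecting — the choice
matters only for the measure-zero case of an exact 50/50 split).  Mixed
windows are retained for training and testing, as annotated field data are
in practice.

## Feature conventions

Eleven characteristics × four streams = 44 features, ordered alphabetically
by `<feature>__<stream>` so that serialized models remain valid across runs.

* Moments are population moments (ddof = 0).  Kurtosis is the biased Fisher
  excess m₄/m₂² − 3, with a constant window defined as 0; IQR uses the
  type-7 (linear interpolation) percentile rule.
* Spectral quantities use the raw one-sided periodogram |X(f)|² of the
  un-tapered, un-detrended window.  Spectral entropy is the natural-log
  Shannon entropy over **all** bins, DC included, and is 0 for an
  identically zero window.  Dominant frequency **excludes** the DC bin:
  magnitude streams carry a ≈1 g offset that would otherwise make the
  feature constant.  Both DC choices are arguments on the extraction
  functions.  Bins below 1e−12 of the spectral peak are treated as zero so
  that a constant window reports 0 Hz at every window length, not only at
  lengths where the FFT produces exact zeros.
* Zero-crossing counting is strict after mean-centering; exact zeros inherit
  the previous non-zero sign (leading zeros the first non-zero sign).  A
  signal that touches zero without changing sign therefore does not count.
* SA = Σw/fs and ASA = Σ|w|/fs; on magnitude streams the two coincide.

Every spectral/area/crossing feature is tested against independent
brute-force implementations (explicit O(n²) DFT, naive loops) to 1e−10
relative error.

## Classifier

The ensemble follows the randomized-split design that suits embedded
deployment: per node, 128 candidates are drawn — feature uniform among the
44 (with replacement), threshold uniform on that feature's range within the
node — and the candidate with the largest Gini impurity decrease wins, first
drawn winning ties.  Trees are grown on bootstrap bags (size = training
size, drawn with replacement) without a depth bound, stopping on purity,
range degeneracy, or the one-sample leaf minimum.  Leaves store class
frequencies; the ensemble probability is their mean across trees and the
label its argmax, ties resolved by the fixed order lying < standing <
walking.  The split criterion and candidate scheme are configurable; Gini
was chosen as the standard impurity for classification forests.

The 70/30 split stratifies per class by shuffling within class and rounding,
so train/test ratios match the pooled table within one window.  Windows are
pooled before splitting (the pooled-window design); a grouped split that
assigns whole bouts to one side is available (`groups=` argument) for users
worried about leakage through the 50 % overlap, but is off by default for
fidelity to the pooled design.

All randomness — bouts, noise, split, bags, candidates — descends from one
root seed through named CRC-32-keyed sub-streams (`ethogram.rng.substream`),
so each stage is independently reproducible and experiment manifests need
only record the root seed.

## Metrics and agreement

Confusion matrices are observed × predicted (rows × columns).  Per-class
metrics come from the one-vs-rest collapse; overall accuracy is trace/total,
the multiclass generalization of (TP+TN)/total.  Metrics with empty
denominators are reported as NaN and listed in `MetricSet.undefined` rather
than silently zeroed.

Ear↔collar agreement is Cohen's weighted κ with linear weights
w_ij = |i−j|/(k−1) over the fixed class order — the "equal weights"
convention of the R `irr` package — computed on the two classifiers'
predicted labels over time-aligned test windows (same replicate and start
sample; windows present on one side only are dropped).  Because the classes
are nominal, an unweighted variant is provided and cross-checked against
scikit-learn's `cohen_kappa_score`.

## Energy model

In classification mode the IMU samples continuously, so bytes processed per
hour (fs × 3600 × 14 B) are window-independent; the window size sets how
often the processor reads a sample batch (floor(3600/w) per hour) and how
fast the 256 B SRAM buffer of 8 B classification records fills
(floor(256/8) × w seconds per flush; flushes per hour rounded half-up, which
is the rounding that matches the reference device's published counts).  The
14 bytes/sample figure is derived from the reference byte counts
(672 B / 48 samples).  The per-event energy constants
(0.277651 µA h/acquisition, 0.261103 µA h/flash write) are least-squares
calibrations to bench measurements of the reference logger, not physical
specifications — they are `DeviceProfile` fields, clearly separated from the
exact integer arithmetic.  Battery life uses a 365.25-day year:
years = capacity × 1000 / drain / 8766.

## Synthetic data: what it emulates, and what it does not

The generator is the package's substitute for field data and defines the
conditions under which the pipeline is validated:

* **Bouts**: a semi-Markov chain — successive bouts never repeat a label,
  the next label is drawn proportionally to configurable weights (equal by
  default), durations are exponential with means lying 240 s, standing
  120 s, walking 60 s.  These means give realistic sheep bout structure and
  mixed-window fractions of roughly 1.5–5 % across the 3–7 s windows,
  and imply long-run time shares (π-weighted mean durations) of ≈57/29/14 %.
* **Accelerometer**: per bout, a gravity vector of 1 g in a random fixed
  orientation plus i.i.d. Gaussian axis noise — SD 0.02 g lying, 0.08 g
  standing, 0.10 g walking; walking adds a 1.5 Hz sinusoid of 0.35 g along
  a random direction; standing adds brief head-movement bumps (Poisson
  0.1 /s, 0.5 s half-sine, 0.15 g).
* **Gyroscope**: Gaussian axis noise with SD 5/20/60 deg/s for
  lying/standing/walking, walking adds an 80 deg/s gait oscillation; the
  whole gyroscope signal is multiplied by a position gain — ear 2.0,
  collar 1.0 — so the two positions differ only by that gain for a given
  seed.

These values are the package's own defaults, chosen once to reproduce the
qualitative ordering seen in published field recordings (lying ≪ standing <
walking in both magnitudes; ear gyroscope noisier than collar).  They are
*not* fitted to any real dataset: no grazing or running, no orientation
drift within a bout, no sensor bias, no 16-bit quantization, no recording
dropout.  Passing tests therefore demonstrate that the pipeline recovers
structure of this kind when it is present — windows at 16 Hz/7 s classify at
≳99 % here versus ~91–95 % in field studies — and the *relative* patterns
(lying easiest, standing↔walking confusion, mixed fraction growing with
window length, near-perfect ear↔collar κ) rather than absolute field
accuracies.

## Problem sizes

Default experiment durations are 3600 s per configuration (the acceptance
pipeline uses 7200 s at 16 Hz), giving ≈1000–4800 windows per cell —
enough for stable stratified splits (≥ 100 windows for the rarest class)
while keeping a full grid run in the low minutes on one core.  Durations,
rates and window sizes beyond the study grid are ordinary configuration
values.

## Known limitations

* The forest stores nested-dict trees and predicts by per-row traversal;
  fine for 10³–10⁴ windows, not tuned for 10⁶.
* The κ pairing assumes both positions were windowed from the same
  annotation at the same rate; comparing devices with different clocks would
  need resampling, which is out of scope.
* Undefined metrics propagate as NaN; downstream table consumers must not
  coerce them to 0.
* The energy model is duty-cycle arithmetic with calibrated per-event
  constants; it does not model IMU register configuration, radio, or
  storage exhaustion in raw-capture mode.
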