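# ethogram

Classification of sheep behaviour — **lying**, **standing**, **walking** —
from body-mounted inertial sensors (tri-axial accelerometer + gyroscope on an
ear tag or a neck collar), built for people studying how the three design
choices that dominate such systems interact:

* **sampling frequency** (8, 16 or 32 Hz),
* **window size** (3, 5 or 7 s, with 50 % overlap),
* **sensor position** (ear vs collar),

and what each choice costs in **embedded energy** when the classifier runs on
the device itself.

## The method

The raw axes are never used directly.  Each recording is reduced to four
streams: the accelerometer magnitude Ā = √(Aₓ² + A_y² + A_z²), the gyroscope
magnitude Ḡ (same form), and the first differences of each.  Streams are cut
into windows of *w* seconds whose starts advance by *w*/2; a window spanning a
behaviour-bout boundary is *mixed* and takes its predominant label.  Eleven
characteristics are computed on every stream of every window — IQR, kurtosis,
mean, SD, min, max, zero crossings, spectral entropy
SE = −Σ PSDnorm(f)·log PSDnorm(f) with PSD(f) = |X(f)|², dominant frequency,
signal area SA = Σ Mag/fs and absolute signal area — giving a 44-dimensional
feature vector.

Windows are split 70/30 with per-class stratification and classified by a
bagging ensemble of eight decision trees; at each node a tree draws 128 random
(feature, threshold) candidates and keeps the one with the largest Gini
impurity decrease, growing until pure with a one-sample leaf minimum.
Performance is reported as a confusion matrix (rows = observed, columns =
predicted), per-class precision / recall / F-score / specificity, overall
accuracy, and — between the ear- and collar-based classifiers — Cohen's
weighted κ with linear weights.

A companion energy model turns (fs, w) into per-hour duty-cycle counts
(sample acquisitions, SRAM-buffer flushes to flash) and battery-life
projections for a 270 mA h cell.

Because field recordings of this kind are rarely shareable, the package ships
a first-class synthetic-data generator (`ethogram.synthetic_data`) that
emulates the structure such data have: alternating exponential behaviour
bouts, a near-constant low-noise gravity signal when lying, intermediate
noise with head-movement transients when standing, a ~1.5 Hz gait
oscillation when walking, and an ear-mounted gyroscope that swings harder
than the collar's.

## Worked example

```python
import ethogram as e

cfg = e.default_config(duration_s=3600.0, fs=16.0, position="collar", seed=1)
annotation = e.generate_bout_sequence(cfg)          # behaviour bouts
recording  = e.synthesize_recording(annotation, cfg)  # 6-axis IMU signal
samples    = e.align(recording, annotation)           # 4 labelled streams
windows    = e.segment(samples, 7.0)                  # 7 s windows, 50 % overlap
table      = e.features_table(windows, position="collar")   # 44 features each

train, test = e.split_train_test(table, 0.7, seed=1)
model       = e.train_forest(train, e.ForestConfig(seed=1))
predicted, _ = e.predict(model, test)

cm      = e.confusion_matrix(test["label"].to_numpy(), predicted)
metrics = e.compute_metrics(cm)
print(cm.to_frame())
print(f"overall accuracy: {100*metrics.overall_accuracy:.1f}%")
```

prints

```
predicted  lying  standing  walking
observed
lying        162         0        0
standing       0       115        2
walking        0         0       29
overall accuracy: 99.4%
```

One hour of synthetic data yields 1027 windows (719 train / 308 held out,
3.6 % mixed).  Lying is classified perfectly — it is by far the least
variable signal — and the only errors confuse standing with walking, the two
behaviours whose magnitudes overlap.  The per-class table
(`metrics.to_frame(as_percent=True)`) shows lying F-score 100.0 %, standing
99.1 %, walking 96.7 %.  Synthetic data are cleaner than field recordings,
so these figures sit above what real deployments report; the *ordering*
(lying easiest, standing↔walking the dominant confusion, accuracy growing
with window size and rate) is the behaviour the generator is built to
reproduce.

The energy side:

```python
print(e.energy_table(16.0))          # duty-cycle table for 3/5/7 s windows
print(e.battery_life_years(10.0))    # -> 3.0800 (years at 10 µA h per hour)
```

At 16 Hz a 3 s window forces 1200 sample acquisitions and 38 flash writes
per hour; a 7 s window needs only 514 and 16 — the arithmetic behind
preferring long windows on battery-powered tags.

The same sweep end-to-end over every configuration:

```sh
ethogram grid --seed 1 --duration 3600 --out results/grid
```

writes accuracy, κ, mixed-window and energy tables plus per-cell confusion
matrices and a reproducibility manifest.  `ethogram simulate | extract |
train | predict | evaluate | energy` expose the individual stages.

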