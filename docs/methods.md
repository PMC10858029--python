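# Methods

This note records the scientific choices behind `ppgarr`: the synthetic
signal model, each pipeline stage's algorithm and defaults, the feature
set, the evaluation protocol, and the known limitations.

## Synthetic PPG model

Pulsatile classes (normal, bradycardia, tachycardia, VT) are built beat by
beat. One pulse of interval PI is

    p(t) = a1 · g(t; 0.20·PI, 0.08·PI) + a2 · d(t),         0 ≤ t < PI

where `g` is a Gaussian bell (systolic wave) and the diastolic component
`d` is a Gaussian bell centred at 0.45·PI with width 0.12·PI up to its
crest, then an exponential decay with time constant 0.23·PI. All widths
scale with PI, so morphology is rate-invariant. The exponential diastolic
runoff (the windkessel-like decay of real PPG) matters: with a pure
two-Gaussian pulse, the final ~0.2·PI of each beat is flat at ≈0, and after
mean removal in preprocessing the inter-pulse trough minimum can wander
over ~100 ms, which makes foot (onset) localization ill-posed. With the
runoff the trough is V-shaped and the waveform minimum coincides with the
annotated onset to within a few samples. Pulses are laid down on disjoint
consecutive supports (no tail overlap-add); both pulse-boundary values stay
below 5% of `a1`.

Per record, a base heart rate is drawn uniformly from the class range, and
each beat's interval and amplitude jitter multiplicatively. Defaults:

| class        | HR (bpm)  | PI jitter | amp jitter | notch amp a2/a1 |
|--------------|-----------|-----------|------------|-----------------|
| normal       | 60–100    | 0.04      | 0.05       | 0.45            |
| bradycardia  | 30–50     | 0.04      | 0.05       | 0.45            |
| tachycardia  | 110–140   | 0.03      | 0.05       | 0.45            |
| vt           | 140–220   | 0.06      | 0.20       | 0.10            |

VT is thus fast with a diminished dicrotic notch and strong beat-to-beat
amplitude variability. VF has no organised pulses at all: a 0.3-amplitude
oscillation whose instantaneous frequency random-walks (reflected) inside
4–7 Hz, with slow (0.3 Hz) sinusoidal amplitude modulation between 0.7 and
1.0 of the scale, and an empty onset annotation.

Disturbances: sinusoidal baseline wander (default 0.2 Hz at 0.5× the
record's nominal amplitude, random phase), white noise at a configurable
SNR (default 20 dB relative to the clean waveform power), optional spike
artifacts (off by default). Records default to 250 Hz; the study dataset
uses 60-s records, long enough for six 10-s segments per record while
keeping the full acceptance run under a minute. Every record is a pure
function of its seed; per-record seeds derive from the global seed via a
`SeedSequence`, so streams are independent but reproducible.

**What the generator does not emulate:** motion artifacts, sensor
decoupling, heterogeneous morphologies across subjects, ectopic beats,
multi-arrhythmia records, and the class-overlapping rate distributions of
real ICU alarms. Passing tests on these synthetics demonstrates that the
pipeline recovers planted structure — not that the same accuracy holds on
real recordings, where class overlap is substantially larger.

## Preprocessing

Order: bandpass → smooth → baseline removal → normalize → segment.

* **Bandpass** 0.05–30 Hz, 4th-order Butterworth applied forward-backward
  (zero phase) so landmark timing is not shifted. The 0.05 Hz pole's time
  constant is long; the reflect padding is extended to 0.5/f_low seconds,
  otherwise the startup transient measurably distorts the central region.
* **Smoothing**: centred moving average, default 0.05 s (odd sample count,
  edges shrink) — short enough to preserve the notch at rates ≤ 180 bpm.
* **Baseline removal**: multilevel db4 DWT; the approximation at depth
  L = min{L : fs/2^(L+1) ≤ cutoff} is zeroed. Default cutoff 0.25 Hz
  (L = 9 at 250 Hz, approximation band [0, 0.244] Hz). The cutoff must stay
  below the slowest physiological fundamental — 30 bpm = 0.5 Hz — with
  margin: a 0.5 Hz cutoff (band [0, 0.488] Hz) visibly destroys slow
  bradycardia records. The 0.2 Hz wander sits inside the zeroed band and is
  attenuated ~80% (the soft DWT band edge leaves a small residual).
* **Normalization**: per-record min-max to [0, 1] (z-score available);
  constant signals map to zeros by convention, and a perfectly constant
  record short-circuits the chain so numerical filter residue is not
  inflated into [0, 1]. Per-segment renormalization is available but off by
  default.
* **Segmentation**: consecutive non-overlapping 10-s windows from t = 0;
  a trailing remainder is discarded; segments inherit the record label.

## Delineation

* **Valleys**: local minima with prominence ≥ 0.3× the segment range and
  spacing ≥ 0.25 s (240 bpm refractory). The left end is padded so an onset
  on the segment's first sample is detectable; a boundary at the right end
  belongs to the next segment. On noise-free synthetics the detected foot
  sits a consistent ~20 ms before the nominal onset (filtering rounds the
  foot), well inside the 40 ms matching tolerance used for ground-truth
  recovery.
* **Peaks**: the global maximum strictly between consecutive valleys.
* **Dicrotic notch**: a notch is declared only when the first derivative
  has an interior local maximum after the peak — a re-acceleration toward
  the diastolic wave. (A curvature criterion alone is insufficient: the
  concave-up tail of a notchless Gaussian decay reaches ~44% of the pulse's
  peak curvature.) The notch start is the maximum of the second derivative
  between peak and re-acceleration point (onset of the concavity change);
  the notch end is the next minimum of |first derivative| — the diastolic
  crest, or the flattest point when the diastolic wave is only a shoulder.
  Derivatives are taken on a lightly smoothed (20 ms) copy. Absence is
  coded per pulse.
* **Quality mask**: a pulse is invalid if its interval is outside
  [0.25, 2.4] s (25–240 bpm), its amplitude is below 10% of the segment
  range, or it contains an interior trough with prominence ≥ 25% of the
  pulse amplitude. The third gate is what rejects VF: the 0.25 s spacing
  gate would otherwise convert 4–7 Hz oscillation into pseudo-pulses with
  plausible intervals, but those "pulses" contain deep internal troughs. A
  segment is analyzable iff ≥ 3 pulses are valid.

## Features (41 slots, fixed order)

Morphological (26): mean and sample SD (n−1; singleton SD = 0) of the ten
per-pulse measures {sa, Da, SA, DA, St, Dt, PI, PPI, FWHM, Nt}, then the
means of six ratios {Da/sa, DA/SA, Dt/St, St/PI, FWHM/PI, sa/St}. Measures
are defined from landmarks: sa = peak − onset value; Da = diastolic-crest −
onset value (0 without a notch); SA/DA = trapezoidal areas onset→notch
start and notch start→end of pulse (onset baseline subtracted; all area to
SA without a notch); St = onset→peak time; Dt = PI − St; FWHM = width of
the contiguous region around the peak above onset + sa/2, with interpolated
crossings; Nt = onset→notch-start time; PPI = peak-to-peak time to the next
pulse (absent for the last pulse; absent values are excluded from their own
statistics).

Statistical (7): mean, SD, skewness, excess kurtosis, RMS, IQR, Shannon
entropy (natural log) of the 16-bin amplitude histogram.

Spectral (8): Welch PSD (4-s Hann windows, 50% overlap — ≥ 2 averages per
10-s segment at 0.25 Hz resolution): dominant frequency in [0.5, 10] Hz,
implied HR (60× dominant frequency), band powers in [0.5, 2], [2, 5] and
[5, 10] Hz, relative cardiac power ([0.5, 5]/[0.05, 15]), spectral entropy
and centroid over [0.05, 15] Hz.

Unanalyzable segments (typically VF) receive fixed imputed morphology —
amplitude/area/ratio slots and all SDs 0, PI and PPI means set to the
segment duration — while statistical and spectral slots are computed
normally, so every segment yields 41 finite values and VF remains
classifiable. Feature slots carry descriptive names (`sa_mean`, `pi_sd`,
`dom_freq_hz`, …) in a fixed documented order.

## Selection and evaluation

Features are standardized (train-fold statistics only; constant columns
flagged and passed through as zeros) before PCA. Loadings are eigenvectors
of the sample covariance with a deterministic sign (largest-magnitude entry
positive). Feature relevance = max over the leading components of
|loading| weighted by that component's explained-variance ratio, using the
smallest component count explaining ≥ 90% of variance by default; ties
break by feature index.

Cross-validation is grouped and stratified: whole source records are dealt
to folds (shuffled per class, greedily balancing per-fold class counts), so
segments of one record never straddle the train/test boundary — the
leakage-safe default given that 10-s segments of one record are strongly
correlated. Standardization, PCA and feature sub-setting are refit inside
every training fold, including for the accuracy-vs-components and
accuracy-vs-selected-features curves; a global (leaky) PCA mode exists only
as an explicit opt-in for curve comparisons.

Classifier defaults: decision tree (Gini, unlimited depth); k-NN
(Euclidean, k = 5); RBF SVM (C = 1, kernel scale by the median heuristic on
pairwise training distances, one-vs-one multiclass); ensemble = bagged
decision trees, 100 learners. All stochastic elements are explicitly
seeded; undefined metrics (0/0, e.g. sensitivity of a class absent from a
fold's test rows) are reported as NaN, never silently 0. Overall accuracy
is the pooled (micro) accuracy of the cross-validated predictions.

## Numerical conventions

Indices are 0-based; pulses tile the inter-valley span with the shared-
endpoint rule (each valley ends one pulse and starts the next). Min-max of
a constant signal is all zeros. Histogram entropy treats empty bins as
contributing zero. The depth rule for the DWT and the filtfilt padding are
tied to fs and the band edge as described above, so the defaults adapt to
other sampling rates.

## Limitations

The delineator assumes a single systolic peak per beat and will mis-segment
pulsus bisferiens or severe dicrotism; no motion-artifact rejection is
attempted; a single sampling rate per run is assumed; the classifier
defaults are not tuned (no hyperparameter search), because on the synthetic
study conditions the classes are separable without it. Results on the
bundled synthetics bound what the code does, not what any clinical dataset
would yield.
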