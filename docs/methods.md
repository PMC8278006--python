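# Methods

This note documents the models, conventions and numerical choices behind
`aisquant`, in the spirit of a package methods appendix: what each
procedure assumes, which knobs matter, and what the synthetic-data tests do
and do not demonstrate about real data.

## Line-profile quantification

**Model of the measurement.** A fluorescence line profile is a uniformly
sampled 1-D trace `I(x_j)`, `x_j = j·p` with pixel size `p` (μm), extracted
as the mean across the 3–4-pixel width of a rectangular ROI traced along a
neurite in a sum-projected confocal stack. Background is assumed additive
and spatially flat at the scale of the image: the mean of an off-neurite
region is subtracted from every sample, and negative residuals are kept
(clipping would bias dim dendritic signals upward).

**AIS extent.** Boundary detection runs on a 3-point centered moving
average of the background-subtracted profile (edge windows shrink so the
length is preserved). The peak is the first sample attaining the smoothed
maximum — ties break proximally, matching the expected proximal peak of AIS
scaffold proteins. Walking outward from the peak, each boundary is the last
sample whose smoothed value is still at or above 15% of the smoothed peak;
if the signal never falls below threshold before the ROI edge the boundary
is clamped there and flagged. The reported length is the **pixel extent**
`(end − start + 1)·p`: each boundary sample contributes its full pixel.
Because the true continuous crossing lies within the boundary sample's
pixel on each side, this convention is an unbiased discretization of the
crossing-to-crossing distance; counting only the inter-index distance
`(end − start)·p` systematically underestimates it by about one pixel. On
noiseless Gaussian bumps the detected length matches the continuous
solution `2σ√(2 ln(1/0.15)) ≈ 3.896σ` to within one pixel for σ ≥ 5 px,
which is the accuracy floor set by sampling; smoothing adds only an
O(p²/σ²) perturbation.

**Integrated sums and the axo:dendritic ratio.** The integrated sum of a
segment is the sum of the *unsmoothed* background-subtracted intensities
over the segment divided by the segment length `(end − start)·p` in μm —
smoothing is used only for boundary placement, so the reported intensities
are free of edge bias. (The segment-length denominator is the conventional
inter-index distance; the boundary length above deliberately uses the pixel
extent, and the two conventions are documented here precisely because they
differ by one pixel.) The AIS sum runs over the detected extent — the
quantity of interest is protein accumulated in the AIS — while the dendrite
sum runs over the full traced 15 μm with no 15% rule, since dendritic
signal has no peaked structure to bound. The axo:dendritic ratio is their
quotient; when the dendritic sum is non-positive the ratio is flagged
undefined rather than returned as an infinity. A config switch
(`length_unit: px`) divides by pixel count instead of μm for both sums;
since the ratio is scale-free, the adr is identical under either unit.

**Normalization.** `normalize_to_control` divides each neuron's AIS sum,
dendrite sum and adr by the control-group mean for its analyte, so control
means are exactly 1 and treated values read as fold changes.
`log_transform` (natural log, positive inputs enforced per record) prepares
the values for variance-stabilized group statistics, which are deliberately
out of scope — significance testing belongs to general statistics tools.

## Feature extraction and classification

Profiles are cropped to the first 25 μm (`floor(25/p) + 1` samples, i.e. 90
samples at p = 0.28 μm) to control for length differences, then denoised
with the same shrinking-edge 3-point average. Four statistics summarize the
denoised profile: interquartile range (linear-interpolation quantiles),
skewness `m3/m2^1.5` and excess kurtosis `m4/m2² − 3` with uncorrected
central moments (the convention of common time-series feature libraries; an
alternate estimator is a one-line change), and RMS `√(Σx²/n)`. The
axo:dendritic ratio is appended as the fifth feature — raw by default, with
a config switch for the control-normalized version.

Each classification repeat draws an unstratified uniform split with
`floor(0.7 n)` training neurons (floor is forced by the printed 56/24,
47/21 and 50/22 splits), standardizes features by the training mean and SD
(zero-SD columns fall back to unit scale with a warning), fits an SVC with
RBF kernel, `C = 1` and `gamma = 'scale'` (1/(n_features·var)), and scores
the held-out neurons; accuracy is `(TP+TN)/total`, aggregated as mean ± SD
(ddof = 1) over 100 repeats, with confusion counts summed over repeats.
Repeat *i* uses the child stream `SeedSequence(seed, spawn_key=(i,))`, so
any repeat is reproducible in isolation. The kernel, penalty,
standardization and stratification are all exposed in the configuration;
the defaults are ordinary SVM practice, documented here as this package's
choices rather than as the original study's (which did not state them).

A known small-sample artifact is worth naming: with unstratified splits and
label-free features, held-out accuracy sits slightly *below* 0.5 on average
(class proportions in train and test sets are anti-correlated), so
null-effect cohorts typically score 0.40–0.48 rather than exactly 0.5.

## Current-clamp feature extraction

Spikes are local maxima above 0 mV separated by ≥ 2 ms within the step
window. The voltage threshold scans *backward* from the spike peak to the
last sample whose central-difference dV/dt is below 10 mV/ms and reports
the next sample's voltage: a sustained-crossing rule, so isolated noise
excursions of the derivative cannot fire the criterion early. Rheobase is
the smallest protocol amplitude whose sweep contains a detected spike —
always a grid value by construction. Firing frequency is spike count
divided by step duration (Hz); the curve is queryable at any protocol
amplitude. Threshold, upstroke (max dV/dt between threshold and peak),
downstroke (min dV/dt between peak and the after-spike minimum) and latency
(step onset to first peak) are measured on the first evoked spike of the
rheobase sweep.

Input resistance is the OLS slope of steady-state voltage against injected
current over the spike-free sweeps of the passive protocol (−120…+20 pA,
20 pA increments, 200 ms), with steady state taken as the mean over the
last 25% of the step, converted mV/pA → MΩ. With τ = 50 ms and 200 ms
steps the window retains ≈ 3% of the transient, so Rin is underestimated by
≈ 3.2%; this settling bias is inherent to the window convention (it
vanishes for τ ≲ 20 ms) and stays well inside the 5% recovery tolerance
used in the tests. The membrane time constant comes from a single-
exponential fit (`scipy.optimize.curve_fit`) to the onset transient of the
smallest-magnitude hyperpolarizing step, and capacitance is `1000·τ/Rin`
(ms/MΩ → pF). Both the steady-state window and the τ-fit sweep choice are
conventions, exposed in the API.

## Synthetic data generator

**Imaging cohorts.** The AIS profile is `background + A·g(u)` where `g` is
a difference of two logistic sigmoids (rise rate 0.05, fall rate 0.15 on
the unit length scale) multiplied by a linear taper (slope 0.45, floored at
0.05) — one dominant proximal peak ~5 μm from the AIS start followed by a
decaying plateau, a smooth idealization of measured AIS scaffold profiles.
The generator computes the continuous 15%-crossing geometry of `g` once,
rescales it so the crossing-to-crossing extent equals the target length,
and positions the crossings exactly on pixel-cell boundaries (half-grid
positions); the realized true length stored on the record is therefore an
exact pixel multiple and is recovered *exactly* by the boundary detector on
noiseless data, while noisy recovery degrades gracefully. The bump is
normalized by its sampled maximum so the noiseless peak equals
`background + amplitude` exactly. Dendrites are a flat 15 μm segment.
Stored ground truth (length, peak position and amplitude, compartment
integrated sums, adr) follows the downstream conventions exactly, computed
from the noiseless values.

Defaults describe a realistic cohort: 40 neurons per condition, 30 μm AIS,
peak 1000 a.u. over a 100 a.u. background, dendrite level 150 a.u., pixel
0.28 μm, per-pixel noise SD 30 a.u. Between-cell biological variability is
essential — without it any nonzero effect is perfectly separable and
classifier comparisons saturate — and is modeled as independent lognormal
factors (CV 0.2) on the AIS amplitude and dendrite level plus a Gaussian
jitter (SD 2.5 μm) on the true length, magnitudes typical of
immunofluorescence intensity variability in culture. Treatment effects
multiply the AIS amplitude and dendrite level and shift the length. The
calibrated presets mirror the qualitative inhibitor phenotypes: `strong`
(−8 μm, AIS ×1.35, dendrites ×1.45 — both compartments up, polarity down),
`medium` (−4 μm, dendrites ×1.3), `weak` (−3 μm only). They were chosen
from this effect-vs-variability signal reasoning so that accuracies span
chance to near-ceiling and order strictly.

**Sweep families.** The membrane is a leaky integrator
`τ dV/dt = −(V − rest) + I·R` (pA·MΩ scaled to mV), integrated exactly
between samples. When the deterministic trajectory reaches the spike
threshold, a fixed 2 ms template is pasted — half-cosine rise of 100 mV
over 1 ms from the threshold voltage, half-cosine decay back to rest over
1 ms — and integration resumes from rest, giving repetitive firing whose
rate grows with drive. Gaussian *measurement* noise (SD 0.2 mV, the scale
of a 20 kHz recording after a 2.2 kHz filter) is added after simulation, so
stored spike times, rheobase and template slopes are exact ground truth.
Defaults (Rin 600 MΩ, τ 50 ms, rest −60 mV, threshold −40 mV; 10–100 pA ×
500 ms firing steps, −120…+20 pA × 200 ms passive steps, dt 0.05 ms) give a
closed-form rheobase of 40 pA on the protocol grid.

**Seeding.** One top-level seed; record *i* (and ephys cell *i*) uses
`SeedSequence(seed, spawn_key=(i,))`, so enlarging a cohort never changes
existing records, and identical configs are bit-identical.

**What the synthetic tests do not show.** The generator has straight
neurites, flat backgrounds, Gaussian noise, a single analyte and a
stationary template spike; it contains no curved or crossing AISs, no
bleed-through or photobleaching, no Poisson photon statistics, no
conductance-based spike dynamics, and its profile shape is an idealization.
Passing recovery and ordering tests therefore validates the *estimators and
their conventions*, not performance on any real imaging or recording
dataset; published accuracies from real cohorts are not reproducible from
synthetic data and are not claimed.

## Pipeline

Stages (`simulate`, `quantify`, `features`, `classify`, `ephys`) exchange
plain-text artifacts (CSV tables, JSON reports and sidecars, TIFF for
optional images) inside a run directory; each output carries the SHA-256
hash (truncated) of the scientific configuration — paths, log level and
stage selection are excluded from the hash — and `manifest.json` records
the config echo, resolved seed, package versions and per-file digests. Any
stage can be re-run from the previous stage's files with identical bytes.
Configuration is YAML validated by pydantic models with unknown keys
rejected and typed range errors; an empty document yields defaults with a
generated seed recorded in the manifest. Problem sizes in the test suite
and acceptance script (40 neurons per condition, 100 SVM repeats, 3-cell
electrophysiology grids) are the cohort scales the defaults describe and
keep the whole suite in the tens of seconds.

## Known limitations

* Manual steps of the original imaging workflow (tracing the AIS from MAP2
  fading, excluding crossing AISs) are out of scope; ROIs must be supplied.
* The integrated-sum denominator and the boundary-length convention differ
  by one pixel by design (see above); comparisons across packages should
  check which convention is in use.
* Input resistance inherits the ~3% finite-settling bias described above.
* `firing_frequency_at` reports the rate at any queried amplitude; it does
  not decide which amplitude ("the current threshold") a study intends.
* Vendor binary formats (ABF/NWB/HEKA) are not read; sweep families arrive
  as CSV + JSON.
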