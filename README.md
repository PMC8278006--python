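# aisquant

Quantification of axon-initial-segment (AIS) protein distribution from
fluorescence line profiles, single-neuron treatment classification with a
support-vector machine, and current-clamp feature extraction — with a
synthetic-data generator that provides ground truth for every estimator.

## The scientific problem

The AIS is the proximal axonal domain where action potentials initiate; its
scaffold proteins (ankyrin G, βIV spectrin, neurofascin, Nav channels) are
dynamically redistributed by kinase signaling, and such redistribution is a
form of structural plasticity linked to changes in intrinsic excitability.
A standard way to measure it in cultured neurons is to trace a thin
rectangular ROI along the AIS and a dendrite in a sum-projected confocal
stack and analyze the resulting 1-D intensity profiles. `aisquant`
implements that analysis for anyone who has line profiles (or small images
with ROI annotations) and wants reproducible, tested numbers:

* **AIS extent.** After background subtraction and a 3-point moving
  average, the analyte-specific AIS is the region around the profile peak
  where the smoothed signal stays at or above 15% of the peak:
  boundaries are the outermost samples with
  `s(x) >= 0.15 * max(s)`, and the length is their pixel extent.
  For a Gaussian-shaped bump of width σ this reproduces the closed form
  `L = 2σ√(2 ln(1/0.15)) ≈ 3.896 σ`.
* **Integrated sum.** Summed background-subtracted intensity over a segment
  divided by the segment length (a.u./μm) — computed over the detected AIS
  extent for the axon and over the full traced 15 μm for the dendrite.
* **Axo:dendritic ratio (adr).** AIS integrated sum ÷ dendritic integrated
  sum, a polarity index of a protein's subcellular distribution; cohorts
  can be normalized to their vehicle-control (e.g. DMSO) mean and
  log-transformed for downstream statistics.
* **Treatment classification.** Per neuron, a 5-feature vector —
  interquartile range, excess kurtosis, skewness and RMS of the denoised
  first-25 μm profile, plus the adr — feeds an RBF-kernel SVM. The
  experiment draws a random 70/30 train/test split (sizes
  `floor(0.7 n)` / remainder, e.g. 56/24, 47/21, 50/22 for n = 80, 68, 72),
  z-scores features with training statistics only, and repeats 100 times;
  accuracy is `(TP + TN) / total`, reported as mean ± SD over repeats.
* **Electrophysiology.** From square-current-step sweep families: rheobase,
  voltage threshold (first sample where the rising-phase dV/dt exceeds
  10 mV/ms), firing curve and maximal firing frequency, input resistance
  (OLS slope of the steady-state V–I relation over subthreshold −120…+20 pA
  steps), membrane time constant (single-exponential onset fit),
  capacitance τ/R, spike upstroke/downstroke velocities and latency.

The `aisquant.synth` module generates two-condition cohorts (treatment
effects expressed as AIS shortening, AIS intensity scaling and dendritic
intensity scaling, on top of per-cell biological variability and pixel
noise) and leaky-integrator sweep families, each carrying its exact ground
truth, so every estimator in the package is validated by parameter
recovery.

## Worked example

```python
import numpy as np
from aisquant import synth, quant, classify as clf
from aisquant.synth import SyntheticCohortConfig, EFFECT_PRESETS

cfg = SyntheticCohortConfig(n_per_condition=40,
                            effect=EFFECT_PRESETS["medium"], seed=42)
records = synth.generate_cohort(cfg)

rec = records[0]
bg = rec.ground_truth.background_level
q = quant.quantify_neuron(rec, bg, bg)
print(f"AIS length {q.ais_length_um:.2f} um, "
      f"integrated sum {q.ais_integrated_sum:.1f} a.u./um, adr {q.adr:.2f}")

feats, labels = clf.features_from_cohort(records)
res = clf.run_repeated_classification(feats, labels, n_repeats=100, seed=42)
print(f"accuracy {100*res.mean_accuracy:.1f} +/- {100*res.sd_accuracy:.1f} % "
      f"(train {res.train_size} / test {res.test_size}, {res.n_repeats} repeats)")
```

prints

```
AIS length 30.24 um, integrated sum 2584.3 a.u./um, adr 4.15
accuracy 80.2 +/- 7.2 % (train 56 / test 24, 100 repeats)
```

The first line is one control neuron's detected AIS extent (~30 μm), its
mean background-subtracted intensity per micrometer over that extent, and
its axo:dendritic polarity (AIS ≈ 4× brighter than dendrite per unit
length). The second line says the SVM tells treated from control neurons in
80% of held-out cases for this medium-strength effect (dendritic intensity
×1.3 with a 4 μm AIS shortening); a null effect scores at chance and a
strong effect in the mid-90s, so accuracy orders effect strength.

The same workflow runs from the shell; every stage writes CSV/JSON plus a
manifest with a config hash, and one config + seed reproduces every byte:

```bash
aisquant all --seed 42 --out runs/demo          # defaults (null effect)
aisquant all --config examples/demo.yaml        # medium treatment effect
```

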