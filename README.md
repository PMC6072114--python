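# maldipep

Serum-peptidome profiling by MALDI-TOF mass spectrometry for clinical
classification: can the 2–10 kDa peptide fingerprint of a blood serum sample
tell a patient with monoclonal gammopathy of undetermined significance (MGUS)
apart from a healthy control (HC)?  `maldipep` implements the full analysis
chain such a study needs — spectrum preprocessing, peak-based feature
extraction, technical-replicate quality control, and a polynomial-kernel SVM
classifier evaluated by replicate-grouped nested cross-validation — together
with a synthetic-cohort simulator so that every stage can be tested against
known ground truth without access to patient sera.

It is aimed at mass-spectrometry and clinical-proteomics researchers who work
with linear-mode MALDI profiles acquired as technical replicates and want a
reproducible, seedable, scriptable pipeline rather than a point-and-click
toolchain.

## The method

**Preprocessing.**  Each raw spectrum (m/z, intensity) is square-root
transformed (variance stabilization), smoothed with a Savitzky–Golay filter,
baseline-corrected by subtracting a SNIP (statistics-sensitive non-linear
iterative peak-clipping) estimate, trimmed to the 2–10 kDa analysis window,
and normalized by total ion current (TIC) so intensities sum to 1.

**Features.**  Peaks are local maxima with signal-to-noise ratio ≥ 3 (noise
estimated by a sliding-window MAD).  Peaks are binned across spectra with a
0.17 % relative mass tolerance; bins present in > 90 % of training spectra
become *reference peaks* used to fit a linear (shift + scale) mass-axis
correction per spectrum, and bins present in > 50 % of aligned spectra become
the *spectral features*.  The replicate-by-feature intensity matrix feeds
everything downstream.

**Quality control.**  For each sample, r_avg is the mean pairwise Pearson
correlation of its replicate feature vectors.  The cohort threshold is

    r_th = μ − 3σ

with μ, σ the mean and standard deviation of all r_avg values.  Samples below
threshold shed their worst-correlating replicates one at a time until they
recover; samples left with fewer than two replicates are discarded.

**Classifier.**  A soft-margin SVM with the third-order polynomial kernel
K(u, v) = (γ·⟨u, v⟩ + c₀)³ is trained on individual replicate vectors; a
sample's class is the majority vote over its replicates (ties break by the
sign of the summed decision values).  The three hyperparameters (γ, c₀, cost
C) are tuned by grid search under k-fold cross-validation in which **all
replicates of a sample share a fold** — the grouping that prevents
replicate-leakage optimism.  Generalization is estimated by double (nested)
cross-validation: a 10-fold outer loop whose held-out test folds are never
seen by the 20-fold inner tuning loop.  Performance is reported as accuracy,
sensitivity and specificity (MGUS positive) with a continuity-corrected
McNemar chi-square p-value on the discordant counts.

**Simulator.**  Synthetic cohorts with per-position log-normal peak
amplitudes, between-sample and between-replicate variance components, a
class-dependent multiplicative shift on a subset of discriminative peaks,
exponential-plus-offset baseline, additive detector noise, bounded mass-axis
jitter, detection-limit-driven peak dropout, and occasional corrupted
(intensity-shuffled) replicates.  A ground-truth sidecar records everything.

## Worked example

```python
from maldipep import (SimulationConfig, generate_cohort, SpectrumPreprocessor,
                      PeakFeatureExtractor, ReplicateCorrelationQC, SVMConfig,
                      tune_20fold)

cfg = SimulationConfig(n_mgus=20, n_hc=20, corrupt_prob=0.0, seed=42)
spectra, manifest, truth = generate_cohort(cfg)
print(f"{len(spectra)} raw spectra from {len(manifest.samples)} samples")

processed = SpectrumPreprocessor().fit_transform(spectra)
extractor = PeakFeatureExtractor()
matrix = extractor.fit_transform(processed, manifest=manifest)
print(f"{len(extractor.reference_peaks_)} reference peaks, "
      f"{len(extractor.features_)} spectral features")

qc = ReplicateCorrelationQC()
filtered = qc.fit_transform(matrix)
print(f"QC: mu={qc.mu_:.3f}, sigma={qc.sigma_:.3f}, r_th={qc.r_th_:.3f}, "
      f"{len(qc.report_.removed_replicates)} replicates removed")

grid = SVMConfig(gamma_grid=(0.005, 0.02, 0.05), coef0_grid=(0.1, 1.0),
                 cost_grid=(1.0, 10.0, 100.0))
result = tune_20fold(filtered, grid, k=10, seed=42)
agg = result.aggregate
print(f"10-fold grouped CV: accuracy {agg['accuracy_mean']:.2f} "
      f"± {agg['accuracy_sd']:.2f}, best params {result.best_params}")
```

prints

```
171 raw spectra from 40 samples
33 reference peaks, 40 spectral features
QC: mu=0.919, sigma=0.081, r_th=0.674, 1 replicates removed
10-fold grouped CV: accuracy 0.97 ± 0.08, best params {'gamma': 0.005, 'coef0': 1.0, 'cost': 1.0}
```

Reading: the simulator placed 40 peptide peaks in every spectrum; the feature
stage recovered exactly those 40 m/z positions, with the 33 most reliably
detected serving as alignment anchors.  One poorly correlating replicate
fell below the cohort quality threshold of 0.674 and was discarded.  With a
two-fold intensity shift on 5 of the 40 peaks, grouped 10-fold
cross-validation classifies 97 % of samples correctly.

The same pipeline is scriptable from the shell:

```sh
maldipep run --config config.yaml --out results/ --seed 42      # end to end
maldipep classify --model results/model.bundle --spectra sample/ --out report.json
```

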