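# Methods

This note documents the models, parameter choices and numerical decisions
behind `maldipep`, what the synthetic-cohort generator does and does not
emulate, and the limitations a user should keep in mind.

## Preprocessing

A raw spectrum is processed in a fixed order: square-root transform →
Savitzky–Golay smoothing → SNIP baseline subtraction → trim to the analysis
window → TIC normalization.  The square root stabilizes the roughly
Poisson-like variance of ion counts; smoothing and baseline correction then
operate on homoscedastic data.

* **Savitzky–Golay**: half-window 10 points, polynomial order 3 — common
  practice for linear-mode MALDI profiles sampled near 1 point/Da.  The
  filter reproduces polynomials up to its fit order exactly, so flat and
  linear signal regions pass through unchanged.
* **SNIP**: 100 iterations of the decreasing-window clipped-mean recursion
  (window w = 100 … 1; each point becomes the minimum of itself and the mean
  of its neighbours at ±w).  The estimate never exceeds the signal and is
  non-negative for non-negative input.  Because the recursion is one-sided
  near the array boundaries, its edge influence reaches roughly twice the
  iteration count into the spectrum; for this reason **trimming to the
  2–10 kDa analysis window happens after smoothing and baseline subtraction**,
  so that when the acquired range extends beyond the analysis window (as it
  does for the simulator, which renders a 300 Da margin) all edge effects
  fall outside the window.  TIC normalization is applied to the trimmed
  window only, so preprocessed intensities sum to one over the analysis
  range.
* Negative post-subtraction values are clipped to zero (TIC requires
  non-negative intensities).

## Peak detection and the S/N definition

The SNIP baseline is a minimum-type estimate and therefore sits *below* the
noise band: the subtracted residual retains the (all-positive) noise
fluctuations.  Measuring a candidate peak's height from zero would credit
every noise bump with the full band offset, so the signal-to-noise ratio of
a local maximum is defined as

    snr = (intensity − local median) / noise ,

i.e. height above the local noise floor, with both the floor and the noise
level (1.4826 × median absolute deviation, the Gaussian-consistent scale)
estimated in a sliding 201-point window with reflective edge padding.
Reflective (not constant) padding matters: replicating the edge value
collapses the MAD to zero over the last ~60 points and manufactures spurious
edge peaks.  Detection keeps local maxima with snr ≥ 3 and prunes candidates
closer than the mass tolerance, keeping the most intense.

## Binning, reference peaks and alignment

Peaks pooled across spectra are sorted by m/z and recursively bisected at the
largest gap until every member of a bin lies within the relative tolerance
(0.17 %) of the bin midrange; the reported bin centre is the member median.
The midrange acceptance criterion is deliberate: a set of peaks jittered by
up to ±0.17 % around one true mass spans nearly twice the tolerance, and a
median-anchored criterion would split such a cloud.  The procedure is
independent of the order of the input spectra.

Bins present in more than 90 % of training spectra (strict inequality)
become reference peaks; each spectrum is aligned by a linear shift + scale
fit of its matched peaks onto the references (at least two matches required,
otherwise the spectrum passes through unaligned and flagged).  A linear warp
is the simplest monotone correction and is sufficient for the multiplicative
mass-axis errors (≤ 0.05 %) the simulator produces and instrument drift of
that order.  After alignment, bins present in more than 50 % of spectra
become the spectral features.  Frequencies count technical-replicate spectra,
not samples.

Missing feature cells are filled with the maximum preprocessed intensity
inside the tolerance window around the feature position on the replicate's
warped mass axis (configurable to zero-fill): a replicate that merely failed
peak detection at that position still contributes its local intensity.

## Replicate-correlation quality control

Feature-matrix rows (not full profiles) are the vector space for replicate
correlation; the QC therefore measures agreement exactly where the classifier
operates.  Per sample, r_avg is the mean pairwise Pearson correlation of its
replicate rows; the cohort threshold is r_th = μ − 3σ with the sample (n−1)
standard deviation.  Samples below threshold iteratively lose the replicate
with the lowest mean correlation to its siblings — removing that replicate
can never lower the remaining average, so the recovery loop is monotone —
until they recover or fall under two replicates and are discarded (two
replicates are mandatory).  The threshold computed on a training cohort is
frozen into the model bundle and reused verbatim when classifying unknowns.

**Known limitation.**  The μ − 3σ rule assumes poor replicates are *rare*.
If a substantial fraction of samples contains a decorrelated replicate (in
the simulator: corrupt_prob = 0.05 per replicate at 3–6 replicates/sample
puts one in ~20 % of samples), σ is inflated by the very contamination the
rule should flag, r_th collapses to ~0.3–0.5, and samples holding a corrupted
replicate (r_avg ≈ (n−2)/n of clean) pass the gate untouched.  Algebraically
the rule only isolates shuffle-corrupted replicates when the affected-sample
fraction stays below roughly 6 %.  The package implements the rule as stated
rather than substituting a robust (median/MAD) variant, and the acceptance
suite documents this regime honestly; users screening cohorts with more than
a few percent of corrupted acquisitions should pre-screen replicates by
their mean sibling correlation instead.

## Classifier and cross-validation

The SVM uses the third-order polynomial kernel K(u, v) = (γ⟨u, v⟩ + c₀)³ on
individual replicate vectors; MGUS is the positive class.  Features are
standardized (mean 0, s.d. 1, statistics learned at fit time) by default:
TIC-normalized intensities are of order 10⁻³, at which scale the cubic kernel
is numerically a constant plus a vanishing linear term for any useful γ.  The
flag can be disabled for pre-scaled matrices.

Majority voting assigns the sample label; even-count ties resolve by the
sign of the summed decision values — classifier confidence rather than an
arbitrary class bias.

Fold construction is sample-level, class-stratified and seed-reproducible;
all replicates of a sample share a fold, fold sizes differ by at most one
sample, and every training split contains both classes (single-class
validation folds trigger a logged regeneration with a seed offset).  Tuning
evaluates every (γ, c₀, C) triple on every fold at the sample (majority-vote)
level; the per-fold best triple is recorded, and the overall winner is the
triple with the highest mean validation accuracy, with deterministic
tie-breaks (lowest cost, then γ, then c₀).  Double cross-validation nests
the tuning loop inside a 10-fold outer loop and asserts at runtime that no
outer test sample reaches the inner loop.  Per-fold metrics aggregate as the
arithmetic mean and sample standard deviation.

The default tuning grids span γ ∈ [5×10⁻⁵, 6×10⁻⁴], c₀ ∈ [0.08, 1.1],
C ∈ [90, 240] — appropriate for unstandardized intensity matrices of the
kind legacy toolchains produce.  The synthetic-cohort experiments use a
smaller grid matched to standardized features (γ ∈ {0.005, 0.02, 0.05},
c₀ ∈ {0.1, 1}, C ∈ {1, 10, 100}), which keeps a full nested double CV on an
80-sample cohort under half a minute on one CPU.

McNemar's test uses the continuity-corrected asymptotic chi-square statistic
(|FP − FN| − 1)²/(FP + FN) with one degree of freedom and p = 1 when there
are no discordant predictions.

## The synthetic cohort

The generator emulates the statistical structure the analysis relies on, not
the physics of ionization.  Per cohort it draws 40 peak positions' base
amplitudes log-uniformly in [50, 500] (the default positions are 40 peptide
masses spanning 2–10 kDa at realistic density) and picks 5 discriminative
positions whose mean amplitude is multiplied by the effect size (default 2.0)
in MGUS samples.  Per sample it draws a log-normal biological effect
(σ = 0.35 on the log scale) per position; per replicate a log-normal
technical effect (σ = 0.15), detection-limit-weighted dropout (average
probability 0.05, weighted ∝ 1/amplitude so weak peaks vanish preferentially
— uniform dropout would let a dominant peak disappear and collapse replicate
correlation, which real spectra do not do), and with probability 0.05 the
replicate is corrupted by permuting its peak amplitudes across positions,
which decorrelates it from its siblings while preserving the amplitude
distribution.  Spectra are rendered on a 1 Da grid as Gaussian peaks
(σ = 500 ppm of m/z, linear-mode resolution) over an exponential baseline
(amplitude 300, decay 1500 Da) plus a constant detector offset (30) that
keeps the baseline above the additive Gaussian noise (σ = 3) at high mass,
with a per-spectrum multiplicative mass-axis error uniform in ±0.05 % — half
the downstream alignment tolerance — and clipping at zero.  The acquired
range extends 300 Da beyond the 2–10 kDa window so preprocessing edge
effects stay outside it.  Samples alternate between two acquisition batches;
the first four samples of each class split their replicates across both
batches to exercise the inter-experimental reproducibility estimate.

Not emulated: isotope envelopes, adducts, detector saturation,
peak-shape asymmetry, batch-dependent intensity drift, and correlated
(structured) noise.  Passing tests on this generator therefore demonstrate
the correctness of the pipeline's logic under the stated statistical
assumptions, not performance on real sera; in particular the effect size is
a calibration knob, not an estimate of the real MGUS signal.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on an
80-sample cohort (≈ 355 replicate spectra of ≈ 8 600 points) and the nested
double CV with a 6-triple-per-fold grid; the whole acceptance script
completes in ≈ 30 s on one CPU.  Every source of randomness flows through an
explicit integer seed (NumPy `default_rng`); reruns with the same
configuration and seed are byte-identical, and every written artifact is
stamped with the configuration digest and seed.
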