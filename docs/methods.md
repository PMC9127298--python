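# Methods

This note documents the signal model, the algorithmic and numerical choices
behind `holospect`, and their limitations. The package analyses resting EEG
with a two-layer empirical-mode decomposition ("holo-Hilbert" spectral
analysis), compares groups with cluster-based permutation statistics, and
classifies subjects from selected spectral cells with boosted stump
ensembles. Because no patient recordings ship with the package, every stage
is exercised on synthetic cohorts with planted, therefore exactly known,
ground truth.

## 1. Synthetic cohort model

### What the generator emulates

Each subject contributes eyes-closed (EC) and eyes-open (EO) recordings over
a 26-channel 10–20 montage. Per channel the signal is a sum of
amplitude-modulated carriers over 1/f background noise:

```
x(t) = Σ_osc  gain_ch · A_subj · amp · (1 + depth · cos(2π f_am t + φ_am)) · cos(2π f_c t + φ_c)  +  noise(t)
```

The default oscillator set places most resting power in α (10 Hz carrier,
2 Hz AM), with θ (6/1 Hz), δ2 (3/0.5 Hz), β (20/4 Hz) and γ (40/6 Hz)
contributions. Group structure is planted multiplicatively:

- patient-like groups (EPD, LPD) have β and γ carrier amplitudes scaled by
  0.7 — emulating the reduced fast-rhythm power reported in parkinsonian
  resting EEG;
- the late-stage group (LPD) additionally has θ and δ2 scaled by 1.3
  (slowing);
- eyes-closed recordings have a 2× α gain over eyes-open (Berger effect).

Clinical covariates (HAM-D, BDI-II, MoCA, UPDRS, H&Y, LEDD) are drawn from
truncated normals with group-specific means/SDs. The depression-like score
(`ham_d` by default) is drawn *jointly* with the subject-level amplitude
factor of the θ oscillator from a bivariate normal at a configurable
correlation (default 0.7), so brain–behaviour coupling exists by
construction and its recovery can be tested. The coupled score is left
untruncated so the realised Pearson correlation converges to the target.

A second, cheaper fidelity level (`simulate_spectral_dataset`) plants mean
shifts directly in the subjects × channels × carrier-band × AM-band array
(unit-variance Gaussian cells, the scale of log-ratio-rescaled spectra).
The statistics and classification stages are validated at this level, where
synthesising hours of EEG would add runtime but no information.

### What it does not emulate

No volume conduction or realistic leadfields (channel gains are free
parameters, not dipole projections), no eye-blink/EMG artifact morphology
(the artifact screen is tested with planted amplitude excursions and flat
segments), no non-stationary drift of oscillator frequencies, no missing
electrodes or bad-channel interpolation, and no medication/time-of-day
effects. Effects are multiplicative amplitude scalings; phase–amplitude
coupling beyond sinusoidal AM is absent.

### Key defaults

| Parameter | Default | Rationale |
|---|---|---|
| `n_per_group` | (59, 80, 19) | HC/EPD/LPD sizes matching the clinical cohort the package models |
| `sampling_rate` | 2500 Hz | typical research-amplifier rate; downsampled to 500 Hz for analysis |
| `epoch_ms`, `n_epochs` | 8000 ms, 4 | 8-s artifact-free epochs, enough for a 0.5 Hz carrier octave |
| `noise_amp`, `noise_exponent` | 3 µV, 1.0 | 1/f background at realistic amplitude relative to 4 µV α |
| `amp_cv` | 0.2 | between-subject amplitude variability |
| `score_effect` | 0.7 | strong planted brain–behaviour correlation, testable at n ≈ 100 |

## 2. Two-layer decomposition

First layer: improved CEEMDAN. Stage-matched noise modes (a shared noise
bank decomposed once per realisation) are added at amplitude
`noise_ratio · SD(residue)` (default 0.2); each mode is the average over the
ensemble (default 50) and the residue telescopes, so reconstruction is exact
up to floating-point rounding regardless of ensemble size. Second layer:
plain EMD of each first-layer amplitude envelope.

Numerical choices:

- **Sifting** uses natural cubic splines through mirror-extended extrema
  (2 extrema reflected at each end) and the S-number stop rule (counts of
  extrema and zero crossings within 1 of each other and unchanged for
  S = 4 consecutive sifts, capped at 50 iterations). When the cap is hit
  before S-stability, the last iterate that satisfied the extrema/zero-
  crossing property is returned, so every emitted mode with ≥ 4 extrema is a
  valid IMF while the telescoping residue keeps reconstruction exact.
- **Amplitude envelope** `a(t) = max(spline_envelope(|c|), |c|)`: the spline
  through maxima of |c| can undershoot the signal between knots; taking the
  pointwise maximum guarantees |c|/a ≤ 1 so the direct-quadrature phase is
  defined everywhere and `a · cos θ = c` holds to machine precision.
- **Direct quadrature phase**: θ from `arccos(c/a)` with branch unwrapping,
  avoiding Hilbert-transform edge bias. Instantaneous frequency is the
  phase gradient; non-physical (negative) estimates and dead-envelope
  samples are masked as NaN rather than clamped.
- **Mode count cap** `ceil(log2 N)`: the dyadic-filterbank bound for EMD on
  broadband signals.

## 3. Holo-Hilbert spectra

Power is the squared second-layer amplitude projected onto (carrier IF,
AM IF) cells: log2-spaced fine bins at 8 per octave, aggregated into octave
bands from low-δ (0.5–1 Hz) up to γ+ (128–256 Hz, carrier axis only; the AM
axis stops at 128 Hz). Unmodulated power — the squared second-layer
residue — is kept in a separate leading `trend_AM` row. Samples where the
AM frequency reaches or exceeds the carrier frequency are physically
meaningless and are excluded exactly (zero power above the equi-frequency
line, asserted in the test suite). Spectra are rescaled per cell as
log-ratios to the grand mean across subjects, making cells unit-free and
approximately Gaussian for the statistics stage.

## 4. Group statistics

Cluster-based permutation tests control familywise error over channels ×
carrier bands × AM bands. Cells are adjacent if they share all but one axis
and are neighbours on that axis: sensors within 75 mm on the montage, or ±1
carrier band, or ±1 AM band (`trend_AM` adjacent to the lowest AM band).
Cluster mass is the sum of pooled-variance t values over suprathreshold
cells; the null is the permutation distribution of the maximum |mass| (group
relabelling for independent designs, sign flips for paired). Measured
calibration at the study's dimensions (20+20 subjects, 26 channels, 8×9
cells, 500 permutations, 200 null datasets): familywise positive rate 0.065
at α = 0.05; a planted 1.5-SD contiguous effect (4 frontal channels × 2 AM
bands) is recovered in 50/50 datasets.

Demographics helpers use the RMS-SD Cohen's d, `|m1 − m2| / √((s1² + s2²)/2)`,
and the 2×2 χ² without continuity correction, matching the conventions of
the clinical tables they reproduce.

## 5. Classification

Features are spectral-cell powers (and optionally pairwise ratios). After
pruning features correlated above 0.95 on the training split, chunked
LogitBoost selection ranks features in chunks of 100, keeps 3 per chunk, and
repeats until 3 survive. Seven classifiers (LogitBoost, bagged trees,
GentleBoost, single tree, RBF-SVM with median-heuristic γ, Gaussian naive
Bayes, k-NN with k = 5 capped at n/2 for tiny folds) are compared by pooled
out-of-fold ROC AUC under stratified 10-fold CV, then refit on the full
training split and evaluated on the held-out test split. All boosting is
implemented as weighted least-squares stumps so feature importances are
exact selection counts.

## 6. Acceptance problem sizes

The acceptance suite's replicate counts are the package's own choices,
sized to finish in minutes on one core while keeping Monte-Carlo error
small relative to the tolerances tested:

- signal-recovery checks at 8 s / 500 Hz / ensemble 20 (≈ 20–30 s per
  signal);
- decomposition invariants on 50 random walks of 512 samples (≈ 1 min);
- calibration on 200 null and 50 planted datasets at 500 permutations
  (≈ 3.5 min);
- feature selection over 10 seeds at the 94/64 train/test split (≈ 2.5 min).

The feature-selection plant uses a 2.0-SD shift: at 1.5 SD and n = 94
training subjects against 1872 candidate cells, exhaustive recovery of all
three cells is power-limited (≈ 80% across seeds) for any selector, so the
planted cells would not be unambiguously "discriminative" at that sample
size. `scripts/acceptance.py` re-runs the same computations at reduced
replicate counts (100/25 datasets, 5 selection seeds, 20 random signals) to
stay within a few minutes.

## 7. Limitations

- EMD-family decompositions have no convergence theory; all guarantees here
  are empirical invariants enforced by tests (exact reconstruction, IMF
  validity, dyadic mode counts).
- The synthetic generator's effects are stylised; passing the suite
  demonstrates correctness of the machinery, not clinical validity.
- Cluster-level inference licenses statements about clusters, not about
  individual cells within them.
- Classifier AUCs on synthetic cohorts with planted 2-SD effects are upper
  bounds relative to real patient data.
- The EDF writer targets the 16-bit EDF subset needed here (fixed header
  date for byte-identical reruns); it is not a general-purpose EDF+ library.
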