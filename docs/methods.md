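# Methods

## Signal model and extraction pipeline

The pipeline assumes an eyes-closed resting recording whose informative
content is a narrow-band dominant rhythm between 3 and 14 Hz riding on
broadband background activity. Processing is:

1. **Band-pass** 3–14 Hz, zero-phase (forward–backward) 4th-order
   Butterworth. Zero-phase filtering is applied to the continuous record
   *before* segmentation so epoch boundaries carry no filter transients
   and no phase distortion. The effective magnitude response is the
   squared Butterworth response.
2. **Segmentation** into contiguous, non-overlapping 2-second epochs;
   trailing partial samples are discarded. A 3-minute record yields 90
   epochs of 512 samples at 256 Hz. When more kept epochs are available
   than requested (default 90), the first 90 in temporal order are used
   and the truncation is logged.
3. **Artifact screening** (optional, off by default): an epoch is
   rejected if any channel exceeds ±100 µV. This is a deliberately simple
   automated screen suitable for gross movement/ocular artifacts; it is
   not a substitute for expert review of clinical data, and it is
   disabled for synthetic input, which is clean by construction.
4. **Spectral estimation**: per-epoch, per-channel rectangular-window
   periodogram with no zero-padding, so the bin spacing is exactly
   1/epoch-length (0.5 Hz) and an on-grid sinusoid occupies a single bin.
   The one-sided spectrum is normalized so total power equals the
   mean-square amplitude (Parseval; enforced to 1e-6 relative in tests).
   Spectra are never averaged across epochs before feature extraction,
   because DF is defined within each epoch.

### Feature definitions

- **DF**: argmax of power over bins in [3, 14] Hz. Exact power ties break
  toward the *lowest* frequency — a deterministic rule that is
  conservative for a slowing biomarker.
- **DFV**: sample standard deviation (n−1 denominator) of the DF series.
- **DFP**: percentage of epochs whose DF classifies into each band.
  The printed band intervals (delta ≤ 4.0; theta 4.5–5.5; pre-alpha
  6.0–7.5; alpha 8.0–12.0; beta > 12.0 Hz) leave gaps that no 0.5 Hz bin
  can occupy; for totality the implementation classifies with the
  half-open extension delta [0, 4.25), theta [4.25, 5.75),
  pre-alpha [5.75, 7.75), alpha [7.75, 12.25), beta [12.25, ∞), which
  agrees with the printed intervals at every on-grid frequency.
- **IAF**: per-epoch argmax restricted to [8, 12] Hz, averaged over
  epochs. With no genuine alpha power the estimate sits at the band floor
  near 8 Hz — deliberately so, since this floor behavior reproduces the
  clinically observed pattern of slow-dominant subjects reporting IAF
  medians pinned just above 8 Hz.
- **Derivations**: unweighted channel means over anterior/temporal/
  posterior regions; "global" averages *all* available analysis channels
  (19 with a full montage, i.e. including Cz/C3/C4, which belong to no
  named region). Missing channels shrink the mean and set a completeness
  flag rather than aborting.

Candidate features for statistics/modeling are DF, DFV, IAF and the four
reported prevalence bands (alpha, pre-alpha, theta, delta) × 4
derivations = 28 columns; beta prevalence is carried in the table for
completeness but is not a candidate.

## Statistical layer

- Mann–Whitney U, two-sided. Exact enumeration p when n₁+n₂ ≤ 12 with no
  ties; otherwise normal approximation with tie and continuity
  corrections. Effect size r = Z/√N, signed positive when the *reference*
  group (the non-CF-like group in the intended design) tends larger, so
  preserved-alpha features carry positive r. A pooled sample with zero
  rank variance returns p = 1, r = 0.
- Benjamini–Hochberg FDR applied jointly over all 28 feature×derivation
  tests (one family).
- Per-feature logistic models: outcome ~ feature + age + sex + MoCA,
  maximum likelihood, odds ratio per raw unit (Hz or percentage point),
  Wald 95% CI, BH q over the tested set. Complete separation — likely
  when a synthetic effect is large — triggers a ridge-penalized refit
  (α = 0.01) with standard errors from the penalized Fisher information;
  such results are flagged `separation=True` rather than hidden.
- Correlation pruning: greedy; while any absolute Spearman correlation
  exceeds the threshold (default 0.9, chosen because inter-regional
  correlations of these features run ≈0.94–0.98), the member of the
  worst pair with the higher mean absolute correlation to the remaining
  features is dropped; exact ties drop the later column. The surviving
  count is data-dependent and is not asserted anywhere.
- Elastic net: features standardized; L1 ratio fixed at 0.5; penalty
  strength selected on a log grid (C ∈ [0.01, 10]) by stratified k-fold
  (default 10) cross-validated AUC with an explicit seed; CV-AUC ties
  resolve toward the *stronger* penalty, so saturated discrimination
  yields the sparser model. Apparent and cross-validated AUC are both
  reported and labeled, never conflated.
- Forward selection: intercept-only start, add the feature with the
  largest AIC decrease, stop at no improvement. Non-converging candidate
  fits are skipped.
- ROC/AUC: trapezoidal integration, ties counted ½; verified in tests
  against brute-force pairwise concordance to 1e-12.

## Synthetic cohorts

Each subject is pink-noise background (1/f, configurable exponent) plus a
single oscillator whose band is re-drawn each 2-second epoch from a
per-subject occupancy distribution — epoch-locked switching makes spec'd
occupancies map one-to-one onto measured DFP, giving exact recovery
targets (a flag enables asynchronous, exponentially timed switching for
robustness checks). Backgrounds mix a scalp-shared and a private noise
trace (60% shared amplitude) so regional averages are not trivial copies
of one channel. Oscillator amplitude is set per channel from the
in-band (3–14 Hz) background power at the subject's SNR (preset mean
8 dB ± 2); frequencies take ±0.2 Hz per-epoch jitter and random phase.

The two default presets encode the intended group contrast: the
non-CF-like group is alpha-dominant (mean occupancies 0.55 alpha /
0.22 pre-alpha / 0.07 theta / 0.16 delta; alpha oscillator ~N(9.5, 0.6) Hz),
the CF-like group slow-dominant (0.10 / 0.45 / 0.17 / 0.28; pre-alpha
oscillator ~N(6.2, 0.5) Hz, residual alpha sitting low in the band,
~N(8.8, 0.5) Hz). Subject occupancies are Dirichlet draws about the
preset means (concentration 30). Covariates: age ~N(73, 6) in both
groups; sex male with probability 0.79 (CF-like) vs 0.54; MoCA ~N(19.5, 4)
vs N(24, 2.5), rounded and clipped to [0, 30] — so MoCA is a genuine
confounder for the adjusted models while age is not. Per-subject seeds
derive from the master seed via seed sequences; identical specs produce
bit-identical recordings.

**What the generator does not emulate:** real artifacts (ocular, muscle,
electrode), drowsiness, non-stationary background power, asynchronous
state switching (unless enabled), regional topography of the rhythm
(every channel shares the subject's oscillator), and volume-conduction
structure beyond a shared background trace. Consequently passing tests
establish correctness of the *measurement and inference machinery*, not
clinical effect sizes: synthetic group separation is cleaner than in
patients, and AUCs near 1.0 on the default cohort should not be read as
expected clinical performance.

## Problem sizes and numerical choices

Validation workloads are scaled to desk size as the package's own test
design: parameter recovery uses 60-second single-channel recordings at
128 Hz (30 epochs) over 20 seeds per target frequency; type-I control
uses 200 null cohorts of 4+4 subjects (60 s at 128 Hz) through the full
pipeline in the test suite (100 in the acceptance script), plus 200
directly simulated feature-table cohorts at the statistics layer; the
qualitative end-to-end check uses the full default cohort (29 vs 24
subjects, 3 minutes at 256 Hz, 19 channels). Filter corners and band
edges are exact binary-representable values except 0.5 Hz grid points,
which are exact in floating point; DF/IAF values therefore compare
exactly against grid frequencies in tests.

EDF I/O reads through MNE (labels canonicalized onto legacy 10–20 names,
physical dimensions rescaled to µV); the package includes a minimal
EDF writer — 16-bit quantization over a symmetric physical range, one
1-second record per block — used by the simulator CLI and test fixtures.
Round-trip error is bounded by one quantization step. Recordings whose
EEG channels carry different sampling rates are rejected as unsupported
rather than silently resampled.

## Known limitations

- The reference (recording montage reference) is not modeled; extraction
  is reference-agnostic.
- The amplitude screen is a crude stand-in for expert artifact review.
- Exact Mann–Whitney p-values are limited to small tie-free samples; on
  the 0.5 Hz feature grid ties are common, so clinical-scale comparisons
  effectively use the corrected normal approximation.
- Elastic-net coefficients are reported on the standardized scale and
  are not directly comparable to the per-feature odds ratios.
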