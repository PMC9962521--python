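# Methods

This note documents the models and procedures implemented in `eegsense`,
the parameters that matter, the numerical choices made where conventions
were open, and what the synthetic-data tests do and do not demonstrate.

## Signal model and band decomposition

An epoch is a channels × samples matrix at a known rate (the reference
layout: 10 channels, 1000 Hz, 400 ms, band-limited 0.1–50 Hz). Two
transforms feed the features:

**Haar DWT.** Four levels of the orthonormal Haar analysis,
a_j = (x_{2j}+x_{2j+1})/√2, d_j = (x_{2j}−x_{2j+1})/√2, recursing on the
approximation. Labels follow the decomposition level: D1 = gamma,
D2 = beta, D3 = alpha, D4 = theta, A4 = delta. Since four halvings put the
labelled edges (25/12/6/3 Hz) at a 50 Hz Nyquist, the wavelet stage runs
on the epoch resampled to 100 Hz (polyphase, linear-fit padding so
constants are preserved); the Welch stage keeps the original rate, where a
100 ms window is 100 samples rather than a useless 10. This split is the
package's resolution of an underdetermined design point: the band labels
assume a 50 Hz Nyquist while the source data is sampled at 1000 Hz.

Numerical conventions (chosen here; tested):

* orthonormal (not unnormalised) filters, giving Parseval energy
  conservation (tested to 1e-6 relative) and perfect reconstruction for
  even lengths (tested to 1e-9);
* odd-length levels replicate the trailing sample before pairing —
  deterministic and length-preserving (matches PyWavelets' symmetric
  boundary for the two-tap filter, which the tests use as an independent
  oracle);
* the approximation path equals multiscale coarse-graining up to the
  orthonormal gain: A_k = 2^(k/2) · coarse-grain(x, 2^k), exact for
  lengths divisible by 2^k. This identity is why entropies of the band
  sequences are multiscale entropies at scales 2^k, and why no separate
  coarse-graining pass exists in the pipeline.

**Welch PSD.** Hann window, 100 ms segments, 50 % overlap, per-segment
mean removal, density scaling (scipy). Band powers integrate PSD·Δf over
bins whose *centers* fall in the half-open interval [lo, hi); relative
power divides by the total over the five bands. Default edges are the
wavelet-aligned ones (0.1–3, 3–6, 6–12, 12–25, 25–50 Hz) so spectral and
wavelet features describe the same bands; the canonical clinical edges
(0–4/4–8/8–12/12–30/30–100) ship as the `clinical` preset. With 100 ms
windows the bin width is 10 Hz, so narrow-band power estimates are coarse;
tests that need spectral precision use longer windows explicitly.

## Features

12 per channel-band: `abs_welch`, `rel_welch`, `rms`, `variance`
(N−1 denominator), `cv` = variance/mean (as defined here, variance — not
SD — over the mean; NaN at zero mean), `shannon`, `apen`, `samen`,
`msamen`, and min-max-normalised `*_norm` variants of the three template
entropies. Multi-epoch subjects average feature rows across epochs.

Template-entropy parameters: embedding m = 2, tolerance r = 0.15 × the
series SD (population SD, ddof 0), Chebyshev distance. Conventions:

* **ApEn** uses the classical form φᵐ − φᵐ⁺¹ with self-matches included;
  a printed variant that averages ln nᵢᵐ / ln nᵢᵐ⁺¹ exists behind
  `printed_form=True` but is degenerate (division by ln 1) and not used.
* **SamEn** = ln(B/A), self-matches excluded, both template sets of size
  N−m so a constant series gives exactly 0. B = 0 returns NaN (flagged
  missing); A = 0 returns the guarded maximum ln B.
* **mSamEn** replaces the 0/1 match with D = 1/(1+exp(d − 0.5r)). The
  exponent is read literally; this makes the statistic translation- but
  not scale-invariant. The scale-free alternative exp((d − 0.5r)/r) is
  available via `EntropyParams(msamen_exponent="scaled")` and is the form
  under which full affine invariance holds (both properties are tested).
* **Shannon** entropy bins coefficients into 16 equal-width bins over
  [min, max] (natural log, non-negative). A "number of unique values"
  histogram is degenerate for floating-point coefficients, hence the
  fixed-bin choice; the bin count is configurable.

At the 100 Hz wavelet rate a 400 ms epoch yields band sequences of length
20/10/5/3/3; the theta and delta sequences are too short to embed
(m + 2 = 4), so their template entropies are flagged missing rather than
fabricated, and imputation (training-fold median; inert zero for columns
with no training information) handles them downstream. Min-max
normalisation is always fit on training subjects only and applied
unclipped to test subjects — the fitting population for the normalised
variants is deliberately leakage-free even though this is often left
unstated in applied work.

## Selection

Stages only remove features, in a fixed order: (1) two-test screen — keep
a feature iff a 2000–10000-draw label-permutation test on |mean
difference| (p = (1 + exceedances)/(n_perm + 1), ties count) *and* the
Mann–Whitney U test (exact for combined n ≤ 10 without ties, tie-corrected
normal otherwise) both reject at α = 0.05. No multiple-testing
correction — the screen is marginal by design, and the two tests are
positively dependent, so the per-feature null retention rate sits between
α² and α (simulation-tested ≤ α). The screen applies one shared set of
label permutations to every column, which leaves each column's marginal
null law unchanged while making the stage a single matrix product.
(2) Spearman filter within each band: the later column of a pair with
|ρ| ≥ 0.8 is dropped — deterministic given column order; constant columns
count as uncorrelated. (3) RFE, one elimination per refit; because the
rank-k prefix of a full elimination order is the size-k RFE subset, one
n_target = 1 run per fold serves every size. L1-regularised (embedded)
selection is available as an alternative endpoint.

## Classification and evaluation

Subject-level stratified k-fold (k = 5 default). Inside every training
fold: normalised-variant filling, median imputation, min-max scaling of
all columns (unclipped on the test fold), then the selection pipeline —
nothing is fit outside the fold. The hyperparameter grids: SVM — linear
kernel, C ∈ {0.01, 0.1, 1, 10, 100}; logistic regression — solver ∈
{liblinear, newton-cg, lbfgs} × the same C; decision tree — criterion ∈
{gini, entropy} × splitter ∈ {random, best} (seeded); threshold —
statistic ∈ {mean, min, max, median, mode}. The RFE subset size (1..30)
is swept as part of the grid; ties resolve to the earlier grid row and the
smaller subset (fewer features suit a wearable). The best combination by
mean fold accuracy is refit on all subjects; the fold scaling is folded
back into the final parameters exactly (weights w/span, bias and
thresholds re-anchored), so persisted and exported models consume raw
feature values as a deployed sensor would.

The threshold classifier learns, per feature, the chosen statistic of the
*case-group* training values and the crossing direction (≥ or ≤ ⇒ case)
that maximises training accuracy, and predicts with the best single
feature. The histogram mode is the midpoint of the fullest of 16
equal-width bins. With gating enabled, the first feature (in table order)
whose rule is 100 % PPV-pure (resp. NPV-pure) on training data fires
first and claims its pure label; otherwise the primary rule decides.
Because the min statistic never misses a training case, a PPV-pure gate
is only non-trivial for interior statistics such as the mean.

Decision evaluation is native: linear score w·x + b with the tie
(score = 0) going to control; logistic σ(w·x + b) with case iff ≥ 0.5;
tree rules walked as x[j] ≤ t. Tests verify score- and label-level
agreement with the fitted scikit-learn models. Metrics derive from pooled
fold confusion counts: Acc, Sen, Spec, PPV, NPV (percent, NaN on zero
denominators) and F1 = 2·Sen·PPV/(Sen+PPV).

## Embedded export

`export_model` emits a C-like `int classify(const double *x)` — a single
linear expression, a nested if-then-else listing, or a threshold
comparison chain — plus a JSON coefficient sidecar. Floats are printed
with `repr`, which round-trips exactly, and the replay interpreter parses
the emitted *text* (not the sidecar), so label agreement between artifact
and native model is exact, not approximate.

## Energy model

E_state [mJ] = ticks_state × I_state [mA] × V [V] / R [ticks/s]; the
execution-time factor in the current→power→energy chain cancels. The
scenario total sums the tracked states. The Z1 profile constants
(V = 3.0 V, R = 32768, I_cpu = 10.0, I_tx = 17.4, I_rx = 18.8 mA,
I_lpm ≈ 0) were calibrated by back-solving the reference scenario ledgers
jointly against their published energy cells — ticks and energies
determine each current to three significant figures — and are consistent
with the mote's datasheet; the profile is a named, overridable default.
Per-feature CPU tick costs ship as a fixture (`FEATURE_CPU_TICKS`) so
feature-level budgets can be composed; their sums reproduce the scenario
CPU ticks exactly. The model takes ledgers as given — it does not emulate
a microcontroller, model the radio protocol, or explain why receive ticks
dominate both scenarios.

## Synthetic data

The generator emulates the reference study's shape — two groups of
10-channel, 1000 Hz, 400 ms epochs, 15 subjects per group, ~80 epochs per
subject — with 1/f background noise, band-limited oscillations (Butterworth
band-pass-filtered noise at conventional center frequencies), and white
measurement noise. Group contrast enters through the gamma band
(oscillation power × `gamma_power_ratio^effect_size`) and alpha
regularity (mixing toward a pure 10 Hz sinusoid with weight
min(1, `alpha_regularity`·effect_size)), mirroring where the reference
analysis found its discriminative features. Per-subject log-normal band
gains (σ = 0.1) create between-subject variance; epochs within a subject
share gains. `gamma_power_ratio` = 1.5 is calibrated so one unit of
`effect_size` corresponds to roughly one pooled SD of subject-level
gamma band power after background dilution, making `effect_size` ≈ a
standardized group effect: at effect_size = 3 the realized separation is
"strong" (SMD ≈ 4), at 0 the groups are exactly exchangeable.

All draws derive from `SeedSequence(seed)` spawned per subject and epoch:
datasets are bit-reproducible and invariant to epoch-count changes in
other subjects. What the generator does **not** model: eye-blink/EMG
artifacts, volume conduction and channel correlation structure, 1/f
exponent variation, non-stationarity within an epoch, or μV scaling.
Passing the end-to-end tests therefore shows the pipeline recovers a
planted band-power/regularity contrast under realistic noise and
between-subject variability — it does not validate clinical accuracy on
real EEG, for which the published feature presets and the EDF/CSV readers
are the entry point.

## Problem sizes and runtime choices

The test suite and acceptance script run the end-to-end condition at
15 + 15 subjects × 20 epochs (the generator's 80-epoch default is the
study-shaped setting; 20 epochs keep the checks quick while leaving
within-subject averaging meaningful). Permutation calibration uses 1000
null replicates at 499 permutations; entropy oracles sweep 100 series of
length ≤ 200; wavelet identities sweep 1000 signals.

## Known limitations

* The threshold classifier searches features marginally; interactions are
  reachable only through the gate.
* The Spearman filter's keep-first rule is order-dependent by design;
  reordering columns can change which of a correlated pair survives.
* The screen's shared-permutation vectorisation induces (harmless)
  dependence between per-feature p-values; per-feature independent draws
  are available through `permutation_test` directly.
* Energy figures are analytical, not emulated: they inherit whatever
  idealisation the input tick ledgers carry.
* EDF support targets plain continuous recordings (16-bit, uniform rate);
  annotations and discontinuous records are out of scope.
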