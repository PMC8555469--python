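# Methods

This note documents the models, parameter choices and numerical decisions
behind plvnet, and what the synthetic validation does and does not show.

## Pipeline

Stages run in a fixed order on epoched 16-channel EEG (10-20 montage,
250 Hz, 8 s trials):

1. **Common average reference.** Subtract the instantaneous across-channel
   mean. Linear, idempotent; output channel sums are exactly zero.
2. **Band-pass 8–30 Hz.** Linear-phase FIR (Hamming window, ~1 Hz
   transition, 825 taps at 250 Hz) applied by centred same-length
   convolution, hence exactly zero phase. Zero phase matters because the
   downstream statistic is built from instantaneous phase; an IIR filter
   applied forward–backward would also work but offers no advantage here.
   Filtering is applied to epoched trials; the affected edge samples are
   excluded later via the wavelet validity mask, which is wider than the
   filter's edge region.
3. **Surface Laplacian.** Spherical-spline current-source density
   (Perrin-type splines): G and H matrices from a Legendre series truncated
   at 50 terms, spline order (stiffness) 4, ridge term γ = 1e-5 on the
   diagonal of G, spline coefficients constrained to zero sum via a
   bordered linear system. Electrode positions are idealized 10-20
   coordinates on the unit sphere (packaged CSV); outputs are on an
   arbitrary CSD scale, irrelevant to the amplitude-invariant PLV. The
   implementation is cross-checked in the test suite against MNE's
   independent CSD routine on the same montage (agreement ~1e-13).
4. **Phase extraction.** Complex Morlet wavelet
   ψ(t) = (π f_b)^(−1/2) e^(j2π f_c t) e^(−t²/f_b), sampled symmetrically
   until the envelope falls below 1e-6 of its peak (alpha: ±2.04 s, 1019
   taps; beta: ±1.35 s). Bands: alpha f_c = 10.5 Hz, f_b = 0.3; beta
   f_c = 21.5 Hz, f_b = 0.13. The normalization (π f_b)^(−1/2) is the
   standard complex-Morlet ("cmor") convention. Convolution runs over the
   full 8 s trial; a validity mask excludes half a kernel length at each
   trial edge, and windowed statistics drop masked samples. For the alpha
   band this trims the rest window [0, 3) s to ≈[2.04, 3) s and the MI
   window [4, 7.5) s to ≈[4, 5.96) s — the price of guaranteeing that no
   zero-padding leaks into any phase estimate.
5. **PLV.** For each unordered electrode pair, the inter-trial mean
   resultant length of the phase difference is computed per sample and
   averaged over the window's valid samples (`aggregate="samplewise"`,
   default). The alternative reading of a single time bin — pooling all
   (trial, sample) phasors into one mean — is available as
   `aggregate="pooled"`; for phase offsets that are constant within a
   trial the two coincide in expectation, and neither mode is privileged.
   Left- and right-hand trials are processed separately throughout.
   ΔPLV = PLV_MI − PLV_Rest by key-matched subtraction.
6. **Scales.** Unweighted means over fixed pair sets: global = all
   C(16,2) = 120 pairs; large = 25 left-hub × right-hub pairs; local =
   C3 (C4) paired with its four hub neighbours ("star", default) or all 10
   within-hub pairs (`local_mode="within_hub"`). Star mode is the default
   because the local scale is described as a centre electrode against its
   surround; the within-hub variant is kept since the exact edge set of
   the local network is a modelling choice.
7. **Statistics.** Median split on accuracy (strictly above → High,
   strictly below → Low, at the median → excluded; an odd cohort with
   distinct values loses exactly one subject and yields balanced groups).
   Per (scale, band, window): 2×2 factorial ANOVA on one value per
   subject × hand (trial-averaged PLV — the subject-level unit avoids
   pseudo-replication; a trial-level mode is intentionally not the
   default), F from orthogonal contrasts (the balanced design makes Type
   I/II/III sums of squares coincide), p = (b+1)/(B+1) from B = 999
   permutations. Post-hoc: two-sample permutation t-tests (Welch
   statistic), with exhaustive enumeration available for small samples.
   Bonferroni threshold α/m with m = (windows + Δ) × bands = 6 by default,
   displayed at 3 decimals (0.008).

### Permutation scheme

The two hand values of one subject are strongly dependent (same brain,
same session). The default `subject` scheme therefore restricts the
permutations: the group and interaction nulls shuffle whole subject blocks
(equivalent to permuting group labels at the subject level), and the hand
null swaps the two hand values within randomly chosen subjects. Shuffling
single observations across the board (`manly`, kept as an option together
with `freedman_lane`) destroys the within-subject correlation in the null
ensemble and was measured here to be grossly anti-conservative for the
group effect — a subject-level standardized difference of ~0.8 at n = 6+6
came out at p = 0.001. The restricted scheme is calibrated: under both
i.i.d. and within-subject-correlated null data the empirical rejection
rate at α = 0.05 is ~0.05 for all three effects.

## Synthetic cohorts

The generator reproduces the session bookkeeping — 3 runs × 40 trials
(20 left / 20 right, shuffled within run), 8 s trials, rest 0–3 s, cue at
3 s, 250 Hz — and implements phase coupling with exact ground truth. Each
channel carries a narrow-band source A·cos(2π f_c t + θ) with trial-wise
offset θ; a follower channel copies its driver's offset plus a constant
mean lag μ and a von Mises(0, κ) jitter redrawn per trial. The expected
inter-trial PLV of a coupled pair is then the von Mises mean resultant
length I₁(κ)/I₀(κ), the closed-form recovery oracle (κ = 0 → independent
phases; κ → ∞ → PLV 1). Rest- and MI-phase offsets may use different κ;
the offset crossfades over 0.5 s after the cue. Background noise is
1/f^β Gaussian (β = 1) at a source-to-noise RMS ratio of 2 by default;
sources sit at 10.5 Hz with amplitude 10 µV. The inter-trial interval of
the original task is irrelevant to epoched analysis and is not modelled.

Default class models: both aptitude classes couple C4 to its four
right-hub neighbours; the High class tightens the coupling during MI
(κ = 1.0, expected PLV ≈ 0.45) while the Low class stays at the rest
level (κ = 0.5, ≈ 0.24). The four followers receive mean lags at the
non-trivial 5th roots of unity so the locked cluster sums to ~zero and
does not leak into every channel through the common average (a constant
lag does not change PLV).

Two further features make the cohort realistic rather than minimal:

* **Accuracy model.** Per-subject accuracies are truncated Gaussians
  matching the published post-split group statistics (High 77.17 ± 5.44,
  Low 67.19 ± 2.96, split at 71%), truncated at the 71% boundary — groups
  defined by a median split cannot straddle the median, so the faithful
  emulation keeps the latent classes on opposite sides of it.
* **Idiosyncratic connectivity.** Each subject receives one star-shaped
  coupled cluster (driver + 4 followers, a single κ ~ U(0, 4), random
  lags) confined to the six non-hub channels (F3, Fz, F4, Cz, T7, T8).
  One κ driving ~10 pairs produces the large, stable between-subject
  spread of whole-head mean connectivity that real cohorts show. Without
  it, any localized group effect — even a moderate one diluted 4/120 into
  the global mean — remains statistically detectable at the global scale,
  which contradicts the empirical pattern this pipeline is meant to
  localize; with it, the global and inter-hemispheric averages are
  dominated by subject heterogeneity while the hub-based local scales
  stay clean.

Volume conduction is deliberately not simulated (no shared-source mixing),
so the spatial-filter stages can be validated in isolation; consequently
passing tests show that the statistics and their calibration behave
correctly under the stated coupling model, not that the Laplacian removes
realistic volume conduction, that 1/f noise captures real EEG artifacts,
or that effect sizes transfer to real recordings.

## Problem sizes used in validation

Chosen as the package's standard validation configuration: von Mises
recovery uses 200 noiseless trials per κ ∈ {0.5, 1, 2, 4} (the
mean-resultant estimator's sampling sd at κ = 0.5, N = 200 is ≈ 0.048, so
the ±0.05 recovery band is a per-realization statement); type-I
calibration uses 1000 pure-noise replicates of the 27/27 × 2 design with
199 permutations each; the end-to-end replication uses 20 cohorts of 13
subjects (6+6 after the median exclusion), 120 trials each, alpha band,
999 permutations. The brute-force PLV oracle runs on 5 × 3 × 50 tensors
and agrees with the vectorized path to < 1e-10 (measured ~1e-16).

## Degenerate inputs and tie-breaks

Self-pair PLV, fewer than 2 trials, empty or out-of-bounds windows,
windows with no wavelet-valid samples, duplicate electrode positions,
montages below 5 channels, band edges at or above Nyquist, single-channel
CAR, unbalanced ANOVA cells and all-identical accuracies raise errors
rather than returning values. A t-test on two zero-variance equal samples
returns p = 1 by convention. Accuracy ties at the median exclude every
tied subject. Permutation p-values use (b+1)/(B+1), so p = 0 is
impossible and the smallest achievable p with 999 permutations is 0.001.

## Known limitations

No artifact model (EOG/EMG), no head-model forward simulation, no
realistic volume conduction by default, binary latent aptitude classes
rather than a continuous accuracy–connectivity relation, and the raw
recordings behind the published group statistics are not public — so
numerical agreement with them cannot be checked, only the procedural constants and the
qualitative localization pattern.
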