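# Methods

This note documents the models, defaults and numerical choices behind
`gaspread`, what the synthetic cohorts do and do not emulate, and the
problem sizes used by the test suite and `scripts/acceptance.py`.

## Signal model and spectral reduction

Parcel time courses are epoched −1…5 s around the trigger cue (6 s
trials; the tonic grip phase is 1–3 s). Power is estimated with Morlet
wavelets on a 2 Hz grid from 13 to 79 Hz, skipping the 48–52 Hz
line-noise gap entirely, with `n_cycles = f/2` clipped to [4, 20].
The ceiling of 20 (rather than a more common 10–12) keeps the wavelet's
spectral sd near the top of the gamma band at ~2.4 Hz, so that energy
confined to the 48–52 Hz gap drives less than 10% of the response an
in-band tone of equal amplitude produces; the corresponding time support
stays ≤ 0.25 s above 40 Hz, well inside the ~1 s bursts of interest and
acceptable for 100 ms binning. Epochs carrying real padding (the
simulator generates 0.5 s of extra signal per edge) are trimmed after the
transform; otherwise data are reflect-padded by 0.5 s, so wavelet edge
artifacts never reach the analysis window.

Baseline correction is percent change per trial, region and frequency
against the trial's mean power over −0.8…−0.1 s (subtractive and dB modes
exist behind a switch). The window and mode are declared defaults, not
inferred from any upstream pipeline. Band reduction averages frequencies
inclusively at both band edges (a grid point at exactly 30 Hz would count
in both beta and gamma; the default grid has no such point) and then
averages samples within each 100 ms bin; the bin grid tiles the epoch
exactly (60 bins for a 6 s trial).

A known property of per-trial percent change worth stating: its values
are bounded below by −1, carry a small positive (Jensen) offset away from
the baseline window, and are mechanically anchored near zero inside it.
Consequently the marginal distribution of noise-only band-power bins is
not exactly Gaussian, and empirical tail rates of the ±2 SD rule on
wavelet-derived noise can deviate from the nominal Φ(−2) = 2.28% by a
percentage point or more depending on trial counts. The calibration
property is therefore asserted where its oracle applies — on
Gaussian-valued band-power arrays fed through the same calibration and
scoring code — and the pipeline-level rates are treated as approximate.

## Threshold calibration and spread statistics

Cut-offs are calibrated on the HC group only: for each region × band,
every HC participant contributes their trial-averaged bin values over the
full epoch, and the pooled mean ± 2 × pooled sample SD (ddof = 1) give
one activation/deactivation threshold pair. Pooling over participants ×
bins (rather than an SD per bin) yields a single stable cut-off per
region × band; calibration uses the full epoch, task window included.
Binarization is per trial with strict inequalities (a value exactly at a
cut-off scores 0 — a measure-zero event for continuous data,
deterministic for tests); scoring the trial-averaged time course instead
is available (`statistic="trial_mean"`) and is the matched construction
for calibration checks, since it is the statistic the thresholds
themselves are estimated from. A degenerate SD of 0 collapses both
cut-offs onto the mean and yields all-zero states, not an error.

Counts are trial means of the number of regions in state +1 (or −1) per
band × bin, so they are real-valued in [0, n_regions]. GAS is the mean
gamma activated count over bins whose centers lie in [1, 3] s, closed
interval; on the default grid that is the 20 bins with centers
1.05…2.95 s. The multiplier (2), window and band are configurable.

## Permutation GLMs

Group contrasts and clinical associations are OLS GLMs with mean-centered
confounds (age, sex coded F=0/M=1, missing-MRI indicator). Confounds that
carry no independent information in a given sample (constant, or
collinear with already-included columns — both realistic in very small
cohorts) are dropped instead of producing a rank-deficient design.

Inference is by Freedman–Lane permutation: residualize the outcome on the
confound-only model, permute residual rows, add the confound fit back,
refit the full model, and collect the contrast t. P-values use the
add-one estimator (1 + #{|t*| ≥ |t|}) / (1 + n_perm), so p ≥ 1/(1+n_perm);
when n! ≤ 20 000 the test enumerates all row permutations and reports the
exact fraction instead. Family-wise correction uses the permutation
distribution of the maximum |t| over the whole declared family — for the
group analysis that family is every band × bin activated and deactivated
count plus the scalar gamma and high-gamma window means, analyzed in one
call. All tests are two-sided; default n_perm is 5000. A perfect fit
(residual variance at rounding level) maps t to ±1e12 when the effect is
real and to 0 when the effect itself is at rounding level, so constant
outcomes give p = 1 rather than NaN.

Clinical models regress the clinical score on GAS (plus confounds) within
the ALS group, one family per outcome with no cross-outcome correction;
the modeled direction (score ~ GAS) is a package convention. The
fine-motor subscore is simulated as the sum of two 0–4 scale items.

Behavioral comparisons are Welch t-tests (two-sided, Welch–Satterthwaite
df) with Bonferroni correction over the four metrics; the
summary-statistic form is algebraically identical to the vector form and
lets printed cohort tables be re-tested directly. Both-SDs-zero inputs
are degenerate and reported as t=0, p=1 with a flag, not an error.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:
33 HC / 42 ALS participants by default, 120 trials of 6 s at 250 Hz
(Nyquist 125 Hz > 80 Hz), 52 regions. Each trial contains:

* 1/f-shaped Gaussian background noise (power slope −1), independent
  across regions — the simplest background that makes baseline spectra
  realistic without modeling connectivity;
* a beta oscillation in 6 "motor" regions whose amplitude dips by 60%
  during 0–3 s (movement-related desynchronization; identical in both
  groups, so beta carries no group effect);
* gamma and high-gamma bursts — sinusoid packets with frequency uniform
  in the band, truncated-normal durations, and a flat-topped Tukey
  (α = 0.3) taper — placed in a per-trial binomial draw of regions inside
  the 1–3 s window. The ALS-like group draws more regions
  (gamma 20 vs 7; high-gamma 34 vs 18) and longer durations (e.g. gamma
  1.4 vs 1.0 s), implementing the "broader and longer" phenotype on both
  axes. The Tukey plateau (rather than a full raised cosine) keeps a
  burst's power above threshold for most of its nominal duration, so
  detected counts track planted counts;
* an ongoing gamma-band background in every region, fully suppressed
  during 1–3 s in a per-trial draw of regions (8 expected in HC, 4 in
  ALS) — the substrate for gamma *deactivation*, reduced in ALS.

Amplitudes (burst 0.8, gamma background 4.0 against noise SD 1.0) were
chosen once, from signal-to-threshold margins: because percent-change
power cannot fall below −1, deactivations are only detectable when
center − 2·SD > −1, which caps how strongly HC task activity may inflate
the pooled SD and hence favors moderate burst amplitudes over loud ones.

Per-participant RNG streams are spawned from the master seed via
`SeedSequence(seed, spawn_key=(k,))`, so participant k's data is
identical whether the cohort is generated whole or in part, and every
output is a pure function of (config, seed).

The clinical table plants the spread→severity link: progression rate =
0.4 + slope × z(latent spread) + noise (slope default 0.12), clipped so
the ALSFRS-R score stays in 0…48; the score is rounded to an integer and
the rate recomputed so `rate = (48 − ALSFRS_R)/duration` holds to machine
precision. Ages, sexes, ECAS, UMN and NfL roughly match the target
cohort's marginals; NfL is deliberately independent of the latent spread.
The behavior table draws both groups from one distribution (grip strength
centered on the 12 N task target), with an optional per-metric ALS shift
for power checks.

What the simulation does **not** emulate: sensor-space physics (no
forward/inverse model, no head geometry), inter-regional correlation of
background noise, heteroscedastic or non-stationary noise floors,
artifacts (eye, cardiac, line noise beyond the spectral gap), or any
longitudinal structure. Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — they do not
certify performance on real recordings, where threshold calibration meets
skewed power distributions and between-subject variance the generator
keeps modest.

## Problem sizes in tests and the acceptance script

Full-scale cohorts (75 participants × 120 trials × 52 regions) are
wavelet-transform-bound, so the automated checks run scaled versions
chosen to keep the whole suite in minutes while leaving the tested
properties identifiable:

* calibration tails: 15 participants × 25 regions × 3 bands × 60 bins of
  Gaussian band power (67 500 scored cells);
* permutation FWE: 500 null datasets, n = 40, 10 × 10 element family,
  500 permutations;
* exhaustive agreement: n = 7 designs (5040 permutations enumerated);
* planted-effect recovery: 5 cohorts (3 in the test suite) of 6 HC + 6
  ALS × 6 trials × 52 regions through the full pipeline, 300
  permutations — group GAS separation lands near 8.5 regions with the
  scalar contrast family-wise significant and every significant gamma
  bin inside the tonic window;
* progression-slope recovery: n = 42 ALS with slope 0.15 and noise SD
  0.2 (10 seeds), plus a 60-seed null for KS uniformity of p;
* determinism: a 11-participant, 6-region pipeline run repeated and
  compared by CSV sha256.

At these scales the recovered GAS values (≈5 HC vs ≈14 ALS of 52) sit
below the planted region counts because thresholds calibrated on few
trials are wider than at full scale; the separation, not the absolute
level, is the tested quantity.

## Known limitations

* The wavelet estimator, frequency pitch, baseline window and
  calibration-epoch choices are declared defaults; analyses of real data
  should treat them as tunable and report them.
* Freedman–Lane is approximate in very small samples; the exhaustive
  switch removes Monte-Carlo error but not that approximation.
* The activation model is bin-wise; no burst segmentation (onset/offset
  pairing or duration statistics) is provided.
* The 2-D layout used for maps and videos is a schematic flat-map
  (golden-angle discs per hemisphere), not anatomy.
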