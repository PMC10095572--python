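# Methods

This note documents the models, numerical choices and limitations behind
`alphaerd`. It states no empirical result that the test suite does not itself
compute.

## The generative model

Each subject contributes one rest and one task recording (default 180 s at
256 Hz, 16 channels of the 10–20 montage, linked-ears reference as metadata).
Every channel is the sum of four independent zero-mean Gaussian processes,
all in µV:

1. **White measurement noise**, SD `white_noise_sd` (default 1.5 µV).
2. **1/f background**, synthesized in the frequency domain with one-sided PSD
   `background_1f_scale / f` (default 8 µV²/Hz·Hz) above a 0.5 Hz cutoff. Its
   expected power in any band [lo, hi) is exactly `scale · ln(hi/lo)`.
3. **Lower-alpha oscillator** (8–11 Hz) and **upper-alpha oscillator**
   (11–13 Hz): white noise passed through a zero-phase 4th-order Butterworth
   band-pass and scaled to a target RMS amplitude (defaults 5.0 and 3.5 µV,
   with per-subject lognormal jitter, σ = 0.2). Narrow-band noise rather than
   pure tones keeps the spectrum realistic while the in-band power remains
   computable from the filter's magnitude response; a pure tone would make
   band-edge behaviour degenerate.

Under the task, oscillator amplitudes are multiplied by attenuation factors
`a ∈ (0, 1]`:

| parameter | default | role |
|---|---|---|
| `task_attenuation_alpha2_cc` | `1.02 − 0.004·age` | CC upper-alpha suppression grows with age |
| `task_attenuation_alpha2_ct_tt` | 0.99 | CT&TT upper alpha essentially unchanged |
| `task_attenuation_alpha1` | CC 0.98, CT&TT 0.92 | lower-alpha ERD mainly in CT&TT |
| `left_bias` | 0.95 | extra attenuation of F3/FP1 (left-lateralized language activation) |
| `attenuation_jitter_sd` | 0.1 | between-subject variability of the task effect |

These defaults were chosen once so that the generated world reproduces the
qualitative pattern the pipeline is meant to detect — an age-correlated
upper-alpha ERD confined to the risk-genotype group (target correlation
magnitude near 0.5 in the CC group), lower-alpha ERD in the comparison group,
left-hemisphere dominance, and no genotype difference in verbal-fluency
scores — at effect sizes detectable with ~80%+ power at the default group
sizes (34 + 60; 24 + 48 aged 30–80). Realized per-subject factors are the
mean factor plus Gaussian jitter clipped to [0.05, 1.25]; the upper clip
deliberately exceeds 1 so that individual subjects can show mild
synchronization, as real cohorts do. The *mean* factors are validated to
(0, 1].

With in-band oscillator power `P_osc`, in-band background-plus-noise power
`P_bg` and background share `b = P_bg / (P_osc + P_bg)` at rest, the expected
task/rest power ratio is `(a²·P_osc + P_bg)/(P_osc + P_bg)`, hence

```
ERD% = 100 · (a² − 1) · (1 − b)      (single-oscillator case)
```

which is the recovery target for all parameter-recovery tests.

**Artifacts.** With probability `artifact_epoch_rate` (default 0.1, capped at
0.2) a 4-s epoch receives a 300 µV Hann-shaped transient on every channel —
an amplitude stand-in for movement/ocular artifacts, not a morphological
model. At the default rate, 45 recorded epochs yield 40.5 retained in
expectation, consistent with a 35–40 artifact-free yield after screening.

**Demographics.** Ages uniform over [19, 80]; sex Bernoulli(0.5); *APOE* E4+
probability 0.37; verbal-fluency word counts normal (mean 47.3, SD 14) with
no genotype effect; MMSE 28–30, CDR 0 (screening criteria of a nondemented
cohort). A genotype-specific sex imbalance is deliberately not modeled.

**Determinism.** All randomness derives from `numpy` `SeedSequence([seed,
stream, subject, condition, channel])`, so identical (spec, seed) gives
bit-identical cohorts and streaming generation equals materialized
generation.

## The leakage-aware oracle

`expected_band_power` does not integrate the model PSD over the band
directly. A 4-s rectangular-window periodogram estimates the PSD convolved
with the Fejér kernel, which moves 1–2% of narrow-band oscillator power out
of the band — a bias that does not shrink with recording duration. The oracle
therefore computes the *expected periodogram* exactly: the model
autocovariance (from the component PSDs) is weighted by the triangular
Bartlett lag window and transformed to the 0.25 Hz bin grid, and band power
is the sum over bins with `lo ≤ f < hi`. Empirical band powers converge to
this oracle within 5% at 600 s and 2% at 3600 s (tested at fixed seeds,
averaged over independent channels to keep the Monte Carlo error of a
single-seed check well below the tolerance).

## Spectral reduction choices

- **Window:** rectangular per-epoch periodograms, Bartlett-averaged. This
  keeps Parseval's identity exact (tested at 1e-9 relative), and since ERD is
  a power ratio the normalization convention cancels. A gain-compensated Hann
  option exists (`window="hann"`).
- **Band edges:** half-open `[8, 11)` and `[11, 13)` Hz. At 0.25 Hz
  resolution alpha1 covers the 8.00–10.75 bins and alpha2 the 11.00–12.75
  bins; the 11 Hz bin is never double-counted, and alpha1 + alpha2 equals the
  power over [8, 13) exactly.
- **Epoching:** non-overlapping consecutive 4-s epochs, trailing remainder
  discarded (180 s → 45 epochs).
- **Artifact surrogate:** peak-to-peak threshold, default 100 µV,
  configurable; visual inspection cannot be reproduced mechanically.
  Subjects with fewer than `min_epochs` (default 30) clean epochs are
  excluded with a logged warning rather than failing the run.

## ERD aggregation order

Region power first, ratio second: channel powers are averaged into
Fd/Fs and ERD% is computed on the regional powers. The alternative —
per-channel ERD averaged within a region — is a *different* statistic and is
available via `per_channel=True` for sensitivity analysis; a regression test
pins the default. ERD is undefined for a non-positive rest power and is
scale-invariant (amplifier gain cancels), both asserted by tests.

## Inference

- **One-sample ERD significance:** two-sided one-sample t against 0 (a
  package choice — the t is what the normality screen justifies); a Wilcoxon
  signed-rank variant is available via `one_sample_method="wilcoxon"`.
- **GLM:** OLS `ERD ~ C(genotype) + C(APOE) + C(sex) + age`, type-II F test
  for genotype; `df_den = N − 5` exactly. The default response is the
  subject's mean ERD across Fd/Fs per band (a subject-level model), with
  per-region models emitted alongside; region is not modeled as a
  within-subject factor.
- **Duncan's multiple range test:** critical values from
  `scipy.stats.studentized_range`, protection level `1 − (1−α)^(k−1)` for a
  span of k ordered means, harmonic-mean span size for unequal n, step-down
  protection. For k = 2 the procedure provably reduces to the pooled
  two-sample t, which the tests exploit as an oracle, alongside published
  table values (2.95 / 3.10 at df = 20, α = 0.05).
- **No multiplicity correction** across bands/regions by default, matching
  common practice in this design; `holm=True` appends Holm-adjusted p-value
  columns to the one-sample and GLM tables.
- **Demographic tests:** pooled-variance t (Welch behind a flag); 2×2
  chi-square without continuity correction (Fisher exact behind a flag).
  Summary-statistics variants (from n, mean ± SE) support reconstructing
  printed cohort tables.

## Calibration and power (what the green tests establish)

Replicate-heavy checks (type-I calibration at the no-effect null, detection
power at default effect sizes, permutation-null uniformity) run on
`sample_erd_table`, which draws subject-level ERD values directly from the
generative model: closed-form region powers perturbed by scaled chi-square
noise with `2 · bins · epochs · channels` degrees of freedom — the sampling
distribution of a Bartlett-averaged band power. This is orders of magnitude
faster than signal synthesis and is validated against the signal-level path
by the recovery tests. It treats bands and regions as independent given the
subject, so cross-band covariance of estimation noise is not represented;
calibration of the genotype test is unaffected (subjects remain exchangeable
under the null), but power estimates for *combined* statistics are
approximate.

## Known limitations

- Artifacts are amplitude transients only; no ocular/EMG morphology, so the
  rejection stage is exercised but not stress-tested against realistic
  artifact spectra.
- The 1/f background is stationary; real EEG is non-stationary across 180 s.
- Acquisition-side analog filtering (0.3 s time constant, 45 Hz low-pass) is
  not emulated digitally; it is irrelevant to the 8–13 Hz bands analysed.
- EDF support is a minimal continuous-EDF reader/writer (16-bit, 1-s
  records, µV); EDF+ annotations and other vendor formats are out of scope.
- Only frontal regions are analysed; occipital/temporal channels exist in the
  simulation solely to make montage handling honest.
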