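# alphaerd

Quantitative-EEG analysis of **task-related alpha desynchronization (ERD/S)**
for two-condition (rest vs covert verbal-fluency task) studies with a
genotype-stratified group design, plus a synthetic cohort simulator with
analytic ground truth.

## Who this is for

Researchers analysing classical clinical-EEG recordings: a 16-channel 10–20
montage sampled at 256 Hz, 180 s of eyes-closed rest and 180 s of a silent
letter-fluency task (LFT), with subjects carrying genetic covariates — here a
*CLU* rs11136000 grouping (risk genotype CC vs pooled CT&TT) with *APOE* E4
status, age and sex as controls. Because such datasets are rarely shareable,
the package ships a generator that emulates the whole signal and effect
structure, so every pipeline stage can be validated against closed forms.

## The statistic

Recordings are cut into non-overlapping 4-s epochs; epochs whose peak-to-peak
amplitude exceeds 100 µV on any analysis channel are rejected (an automated
surrogate for visual screening). Per-epoch FFT periodograms (rectangular
window, 0.25 Hz resolution) are Bartlett-averaged and integrated over the
half-open alpha sub-bands **alpha1 = [8, 11) Hz** and **alpha2 = [11, 13) Hz**.
Channel powers are averaged into frontal regions of interest,

```
Fd = (F4 + FP2) / 2        Fs = (F3 + FP1) / 2
```

and the event-related desynchronization/synchronization percentage is

```
ERD% = 100 · (E − R) / R
```

with `E` the absolute band power during the task and `R` at rest. Negative
values are desynchronization (cortical activation). Inference: Shapiro–Wilk
screening, one-sample t tests of group-mean ERD against 0, an OLS general
linear model `ERD ~ genotype + APOE + sex + age` (genotype F test with
residual df N − 5), Duncan's multiple range post hoc test computed from the
studentized-range distribution, Pearson age correlations, and demographic
tests (pooled t, chi-square) — for the full cohort and for a 30–80-year
subcohort.

## Worked example

Simulate the default cohort (34 CC vs 60 CT&TT subjects, ages 19–80) and run
the full analysis:

```sh
alphaerd all --out out/ --seed 1
```

prints the full-cohort genotype GLM table:

```
  band region    factor         F  df_num  df_den            p  n
alpha1   both clu_group 12.800366       1      89 5.633514e-04 94
alpha1     Fd clu_group 11.340643       1      89 1.121759e-03 94
alpha1     Fs clu_group 13.692307       1      89 3.724691e-04 94
alpha2   both clu_group 37.631720       1      89 2.309860e-08 94
alpha2     Fd clu_group 39.603057       1      89 1.142390e-08 94
alpha2     Fs clu_group 32.668162       1      89 1.435048e-07 94
```

— the upper-alpha (alpha2) desynchronization differs strongly between the
genotype groups (df_den = 94 − 5 = 89), while `out/report.md` shows the CC
group's alpha2 ERD growing with age (this run: r = −0.65 and −0.60 for Fd/Fs,
n = 34, p < 0.001) and no age dependence in CT&TT carriers — the effect
structure the generator is parameterized to produce. `out/` also contains
`band_power.csv`, `erd.csv`, per-analysis `stats/*.json|csv` tables and a
`manifest.json` with config hash and output checksums. `alphaerd simulate`
writes EDF recordings plus a metadata CSV for an existing-data workflow
(`alphaerd analyze --in dir/ --metadata dir/metadata.csv`), and
`alphaerd report --figures` renders ERD bar and age-scatter figures.

In library form:

```python
from alphaerd import CohortSpec, RunConfig, run_analysis

result = run_analysis(RunConfig(simulation=CohortSpec(seed=1)))
print(result.reports["full"].glm)
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it simulates the default
94-subject cohort with the given seed, executes the complete spectral → ERD →
statistics pipeline for the full cohort and the 30–80-year subcohort, prints
the subcohort GLM table, and writes the results JSON to `--out`.
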