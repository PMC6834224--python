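# hfsteps

Free-living wearable step-count analysis for heart-failure functional
classification.

Patients with chronic heart failure are graded by the NYHA functional class
(I–IV), a subjective assessment of exercise limitation with notoriously low
inter-rater reliability for the middle classes. Minute-resolution step
counts from a consumer wrist tracker offer an objective proxy: `hfsteps`
implements the full analysis pipeline that compares free-living step-count
summaries between NYHA groups, together with a calibrated synthetic cohort
generator so every stage is runnable and testable without clinical data.

## What it computes

For each patient-day of 1440 per-minute step counts (PMSC) a first
aggregation computes total, mean, SD (n−1), the five-number summary with
linear-interpolation quantiles, IQR, skewness m₃/m₂^{3/2}, Pearson kurtosis
m₄/m₂², and the zero-minute fraction. A second aggregation takes the max,
min, mean and SD of each daily statistic across the monitoring period
(nominally 14 days), and the whole period is additionally summarised as one
concatenated minute stream. Borderline clinical labels are merged into two
analysis groups (I/II + II → II*, II/III + III → III*), and every feature —
plus the demographic variables — is compared between groups with the
tie-corrected Kruskal–Wallis rank test

&nbsp;&nbsp;H = 12/(N(N+1)) Σ n_g (R̄_g − (N+1)/2)², H_c = H / C,
C = 1 − Σ(t³−t)/(N³−N),

with p from the χ²(k−1) upper tail and unadjusted for multiplicity. Features
that are exactly zero for every patient (the quantile-based statistics, a
casualty of ~87% zero minutes) are excluded; all-identical features are kept
with an N/A marker. A small exact permutation oracle (total n ≤ 12) backs
the test for verification.

Zeros are genuinely ambiguous in this data — the tracker records 0 both for
inactivity and for off-body time — so zeros enter every statistic and a
separate adherence report tracks per-patient zero fractions.

## Worked example

```sh
hfsteps run-all --seed 7 --out-dir out/
```

simulates the default study-sized cohort (35 II* and 15 III* patients,
14 days), computes the feature battery, runs the rank-test battery and
writes the report tables. With seed 7 the significant battery includes:

| feature              | median II* | median III* |     H | p       |
|----------------------|-----------:|------------:|------:|---------|
| mean_of_daily_total  |     5486.3 |      3717.1 | 22.59 | 2.0e-06 |
| max_of_daily_total   |    10816.0 |      7171.0 | 25.07 | 5.5e-07 |
| max_of_daily_max     |      124.0 |       111.0 | 30.57 | 3.2e-08 |

Reading: the II* group's median patient averaged ~5486 steps/day (a "low
active" lifestyle, 5000–7499 steps/day) versus ~3717 steps/day for III*
(sedentary, <5000), and the II* group reached higher peak cadence (124 vs
111 steps/min over two weeks). The adherence report shows zero minutes
accounting for a mean 89.3% (SD 2.5%) of each patient's stream — zero
inflation in the range that makes the quantile features degenerate (19
features excluded in this run, 24 significant, 20 not).

The same pipeline runs on real data via
`hfsteps summarize --stream stream.csv --meta meta.csv --out features.csv`
followed by `hfsteps test` / `hfsteps report`; file formats are documented
in `hfsteps.step_io`.

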