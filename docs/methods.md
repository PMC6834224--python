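# Methods

## Data model

A monitored day is a dense vector of 1440 non-negative integer per-minute
step counts (PMSC). The tracker class being emulated records a zero both
when the wearer is inactive and when the device is off-body; the two cases
are indistinguishable in the output, so zeros are kept in every statistic
and a separate adherence view reports per-patient zero fractions. Day
boundaries are taken as given in the input file (a "day" is a local calendar
day of exactly 1440 minutes); partial first/last days are densified with
zeros rather than trimmed, and a `min_days` read option (default 1) can drop
short records. Per-minute counts are validated against a hard ceiling of
300 steps/min — far above observed free-living maxima (~123) but a useful
corruption guard.

The stream file is long-format CSV (`patient_id, day_index, minute, steps`)
in a sparse dialect: zero minutes may be omitted and are restored on read.
An all-zero day is written with one sentinel row so it survives round trips.
Metadata carries the raw NYHA label (`I/II`, `II`, `II/III`, `III`), sex,
age, height, weight, BMI (cross-checked against height/weight within 5%),
handedness and wristband side.

## Regrouping

Borderline clinical labels are merged with the more extreme class in the
mix: I/II joins II (analysis group II*), II/III joins III (group III*). The
rationale is that a borderline patient necessarily exhibits more limitation
than the milder class alone implies. Classes I and IV are outside the study
population and are rejected on input.

## Statistic battery

First aggregation (per patient-day): total; mean; SD with n−1 denominator;
min, Q1, median, Q3, max with linear interpolation between order statistics;
IQR; skewness m₃/m₂^{3/2}; kurtosis m₄/m₂² (Pearson, non-excess); zero
fraction. Central moments use the n denominator without small-sample bias
correction — at n = 1440 the correction is negligible, and the choice is
recorded here for reproducibility. A constant day (typically all-zero
non-wear) has zero variance; its skewness and kurtosis are NaN, the
pipeline's "not computable" marker, while its order statistics are still
reported.

Second aggregation (per patient): max, min, mean and SD of each daily
statistic across days. Days where a statistic is not computable are skipped
for that statistic rather than poisoning the aggregate — this preserves the
battery for patients with occasional all-zero days — and an SD over fewer
than two contributing days is NaN. The whole period is additionally
summarised as one concatenated minute stream (`period_*` features), giving
56 features per patient; conservation laws (period total = Σ daily totals,
period max = max daily max) hold by construction and are property-tested.

Quantile and moment conventions are deliberately uniform across daily
summaries, cross-day aggregates, demographics tables and group medians.
Which skewness/kurtosis estimator and quantile rule the original analysis
software applied is not documented for this battery; the conventions above
are declared, not inferred, and are the common statistical-package defaults.

## Hypothesis testing

Each feature (and each demographic variable, binaries coded 0/1) is compared
between II* and III* with the Kruskal–Wallis rank test using midranks for
ties and the tie correction C = 1 − Σ(t³−t)/(N³−N). p-values come from the
χ²(k−1) upper tail and are deliberately unadjusted for multiplicity;
significance is flagged at .05 and .01. When all pooled values are identical
C = 0 and the test is undefined: such features are reported as N/A rather
than p = 1. Features that are exactly zero for every patient are excluded
from the battery entirely — with ~87% zero minutes this removes the
quantile-based aggregates.

The heavy tying at zero is why tie correction is enabled by default; whether
the original analysis applied it is undocumented, but it is the standard
default in mainstream implementations.

An exact permutation oracle (full enumeration of group assignments, total
n ≤ 12, p = fraction of assignments with tie-corrected H ≥ observed) exists
for verification only; reported p-values always use the χ² approximation,
matching standard practice at the study's group sizes (35/15). Note the χ²
approximation is intrinsically coarse at very small n: exhaustive
enumeration of the exact null shows per-instance deviations from the exact
permutation p of up to ≈0.09 even for balanced groups of 5, an inherent
property of the approximation rather than an implementation artifact.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular patient. Each day: a zero-filled sleep block (Normal length,
default mean 480 min, SD 45, anchored at midnight); with probability
`nonwear_prob_per_day` an extra zero block of exponential length (mean
120 min) at a uniform waking position; a Poisson number of activity bouts
(rate per waking hour × a per-patient × a per-day multiplier) placed
uniformly over waking minutes, each with geometric duration and per-minute
cadence drawn from a right-skewed gamma, rounded and clipped to
[1, cadence_cap]; and with probability `peak_bout_prob_per_day` one bout is
promoted to near-maximal cadence (Normal centred cadence_cap − 12, SD 3).
Overlapping bouts keep the locally faster cadence so the ceiling always
holds.

Heterogeneity has two levels. A per-patient log-normal multiplier on bout
rate (SD 0.22 on the log scale, clipped at ±2 SD) creates overlapping but
distinct patients; the clip guarantees no simulated patient leaves the
observed zero-fraction envelope [0.767, 0.977]. A per-day log-normal
multiplier (mean 1; SD 0.40 for II*, 0.25 for III*) supplies the day-to-day
overdispersion needed for the maximum daily total to sit near twice the mean
daily total, as the published group medians imply; Poisson bout counts alone
are far too regular to produce that ratio.

The frozen presets were calibrated once against the published group medians
and then fixed: group medians of mean daily total ≈5729 (II*) / 3541 (III*)
steps within ±15%, maximum daily total ≈10792 / 5904 within ±20%, two-week
peak cadence ≈123 / 111 steps/min within ±10%, all per-patient zero
fractions inside [0.767, 0.977] (cohort mean ≈87–89%, near the reported
87.3%). `calibration_check` re-verifies all of these by simulating ≥200
patients per group (~8 s). Raw labels are assigned within each group in the
study's 9:26 and 4:11 ratios; demographics (median age ≈55, ≈86% male,
overweight BMI) are cosmetic — they exist so the demographics battery runs
and are not calibrated beyond medians.

What the generator does *not* model: circadian cadence rhythm within waking
hours, weekday/weekend structure, device measurement error, or any
correlation between demographics and activity. Bout placement uniform over
waking minutes is a declared assumption. Consequently, passing tests show
the pipeline's statistics and tests behave correctly on data with the right
marginal structure (zero inflation, bout clustering, heavy-tailed cadence,
group separation); they do not validate clinical claims about real
patients.

## Simulation study sizes

The shipped checks use: 200 random instances (total n ≤ 10) for the exact
permutation comparison; 1000 random patient-days for brute-force oracle
equivalence; 500 replicates of the null configuration (both groups drawn
from the II* preset, n = 35/15, 14 days) for the type-I error of the
daily-total test, asserted inside the 99% binomial envelope of 0.05
([0.028, 0.078]); 100 replicates of the frozen presets for power (≥90/100
significant at .05); and 200 patients/group for calibration.

## Numerical and design notes

- Group "medians" in battery output are within-group medians of the
  per-patient feature, consistent with reporting medians for a
  nonparametric test.
- Percentages in count tables are rounded half-up to integers; battery CSVs
  carry full precision.
- Lifestyle categories: <5000 steps/day sedentary, 5000–7499 low active,
  ≥7500 above low active; the boundary 5000 belongs to low active.
- Patients with a NaN value for some feature (e.g. SD-of-skewness with one
  computable day) drop out of that feature's test only.
- Exit codes of the CLI: 0 success, 2 input/validation error, 3 analytic
  precondition error (e.g. a group with <2 patients).
- SD-labelled outputs are in steps/minute (or steps), never variance units.
- Figures are reproduced as data tables (histograms, five-number
  summaries); no plotting dependency is required.

## Known limitations

Non-wear time cannot be separated from inactivity in this device class; the
pipeline characterises the ambiguity (adherence report) but does not impute
or detect wear time. The χ² approximation's small-sample coarseness is
documented above. The generator's presets encode one plausible
configuration consistent with the published group medians; many other
configurations would match them equally well.
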