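"""Two-stage statistic battery: oracle equivalence, degenerate days,
conservation laws, nonzero histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    make_patient,
    oracle_cross_day,
    oracle_summary,
    random_patient_day,
)
from hfsteps import (
    Cohort,
    DAILY_STATS,
    FEATURE_NAMES,
    NYHAGroup,
    MINUTES_PER_DAY,
    aggregate_days,
    daily_summary,
    feature_matrix,
    nonzero_distribution,
    patient_features,
    zero_profile,
)


def assert_close(a, b):
    if math.isnan(b):
        assert math.isnan(a)
    else:
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


def test_all_zero_day():
    s = daily_summary(np.zeros(MINUTES_PER_DAY, dtype=np.int64))
    assert s.total == 0
    assert s.mean == 0
    assert (s.min, s.q1, s.median, s.q3, s.max) == (0, 0, 0, 0, 0)
    assert s.zero_fraction == 1.0
    assert math.isnan(s.skewness) and math.isnan(s.kurtosis)


def test_single_spike_day():
    """One active minute: quartiles stay 0 because >75% of minutes are 0."""
    counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    counts[300] = 100
    s = daily_summary(counts)
    assert s.total == 100
    assert s.max == 100
    assert s.mean == pytest.approx(100 / 1440)
    assert s.q3 == 0 and s.iqr == 0
    assert s.zero_fraction == pytest.approx(1439 / 1440)


def test_wrong_length_rejected():
    with pytest.raises(ValueError, match="1440"):
        daily_summary(np.zeros(100))


@settings(max_examples=60)
@given(st.integers(0, 2**31 - 1))
def test_daily_summary_matches_brute_force_oracle(seed):
    counts = random_patient_day(np.random.default_rng(seed))
    s = daily_summary(counts)
    expected = oracle_summary(counts)
    for name, value in expected.items():
        assert_close(getattr(s, name), value)


def test_single_day_aggregation_degenerates():
    counts = random_patient_day(np.random.default_rng(1))
    s = daily_summary(counts)
    features = aggregate_days([s], counts)
    for stat in DAILY_STATS:
        value = getattr(s, stat)
        for agg in ("max", "min", "mean"):
            assert_close(features[f"{agg}_of_daily_{stat}"], value)
        assert math.isnan(features[f"sd_of_daily_{stat}"])


def test_two_day_totals_aggregate():
    d1 = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    d1[:10] = 100  # total 1000
    d2 = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    d2[:30] = 100  # total 3000
    features = aggregate_days(
        [daily_summary(d1), daily_summary(d2)], np.concatenate([d1, d2])
    )
    assert features["max_of_daily_total"] == 3000
    assert features["min_of_daily_total"] == 1000
    assert features["mean_of_daily_total"] == 2000
    assert features["sd_of_daily_total"] == pytest.approx(math.sqrt(2) * 1000)


def test_empty_day_list_rejected():
    with pytest.raises(ValueError):
        aggregate_days([], np.zeros(0))


def test_constant_days_skipped_not_propagated():
    """A non-wear (all-zero) day leaves skewness aggregates computable
    from the remaining days."""
    active = random_patient_day(np.random.default_rng(3))
    while np.all(active == active[0]):  # ensure a non-constant day
        active = random_patient_day(np.random.default_rng(4))
    zero = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    features = aggregate_days(
        [daily_summary(zero), daily_summary(active)],
        np.concatenate([zero, active]),
    )
    s = daily_summary(active)
    assert_close(features["mean_of_daily_skewness"], s.skewness)
    assert math.isnan(features["sd_of_daily_skewness"])  # one contributor


def test_patient_conservation_and_order(synthetic_cohort):
    """period totals/maxima conserve the daily values, the 4-aggregate grid
    is ordered, and cross-day aggregates match the brute-force oracle."""
    for patient in synthetic_cohort.patients[:10]:
        summaries = [daily_summary(d) for d in patient.days]
        features = patient_features(patient)
        assert features["period_total"] == pytest.approx(
            sum(s.total for s in summaries)
        )
        assert features["period_max"] == max(s.max for s in summaries)
        for stat in DAILY_STATS:
            expected = oracle_cross_day([getattr(s, stat) for s in summaries])
            for agg, value in expected.items():
                assert_close(features[f"{agg}_of_daily_{stat}"], value)
            if not math.isnan(features[f"mean_of_daily_{stat}"]):
                assert (
                    features[f"min_of_daily_{stat}"]
                    <= features[f"mean_of_daily_{stat}"]
                    <= features[f"max_of_daily_{stat}"]
                )


def test_zero_profile_is_weighted_mean_of_daily_fractions(synthetic_cohort):
    patient = synthetic_cohort.patients[0]
    daily = [daily_summary(d).zero_fraction for d in patient.days]
    assert zero_profile(patient) == pytest.approx(np.mean(daily))


def test_zero_profile_examples():
    assert zero_profile(make_patient("P1")) == 1.0
    spike = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    spike[0] = 50
    days = [spike] + [np.zeros(MINUTES_PER_DAY, dtype=np.int64)] * 13
    patient = make_patient("P2", days=days)
    assert zero_profile(patient) == pytest.approx((14 * 1440 - 1) / (14 * 1440))


def test_feature_matrix_layout(synthetic_cohort):
    matrix = feature_matrix(synthetic_cohort)
    assert list(matrix.columns) == ["nyha_label", "group", *FEATURE_NAMES]
    assert len(matrix) == len(synthetic_cohort)
    assert matrix.index.is_unique


def test_nonzero_distribution_bins():
    counts = np.zeros(MINUTES_PER_DAY, dtype=np.int64)
    counts[10] = 5
    counts[20] = 5
    counts[30] = 7
    cohort = Cohort([make_patient("P1", label="II", days=[counts])])
    hist = nonzero_distribution(cohort, NYHAGroup.II_STAR)
    assert dict(zip(hist.steps_per_minute, hist.n_minutes)) == {5: 2, 7: 1}
    assert nonzero_distribution(cohort, NYHAGroup.III_STAR).empty


def test_nonzero_histogram_additivity(synthetic_cohort):
    """Pooled histogram totals equal the sum of per-patient contributions
    and count exactly the nonzero minutes of the group."""
    for group in NYHAGroup:
        hist = nonzero_distribution(synthetic_cohort, group)
        expected = sum(
            int(np.count_nonzero(p.pooled_counts()))
            for p in synthetic_cohort
            if p.nyha_label in (("I/II", "II") if group is NYHAGroup.II_STAR
                                else ("II/III", "III"))
        )
        assert hist.n_minutes.sum() == expected


def test_group_cadence_support_ordering(synthetic_cohort):
    """By construction the II* cadence distribution extends higher."""
    hi = nonzero_distribution(synthetic_cohort, NYHAGroup.II_STAR)
    lo = nonzero_distribution(synthetic_cohort, NYHAGroup.III_STAR)
    assert hi.steps_per_minute.max() > lo.steps_per_minute.max()
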