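"""Kruskal-Wallis rank test with tie correction, an exact permutation oracle
for small two-group instances, and the batch runner over the feature battery.

Minute-level step features are massively tied (most patients share exact
zeros for entire quantile-based features), so the tie-corrected statistic

    H_c = H / C,   C = 1 - sum_t (t^3 - t) / (N^3 - N)

is used throughout, with H the usual rank statistic and t the sizes of the
tie runs in the pooled sample.  When every pooled value is identical, C = 0
and the test is undefined; the battery reports that case as not computable
(the tables' "N/A") rather than as p = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .nyha import NYHAGroup


class PreconditionError(RuntimeError):
    """An analytic precondition (e.g. minimum group size) is not met."""


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied values receiving the mean rank of their run."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("midranks requires a non-empty sequence")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_correction(pooled: np.ndarray) -> float:
    """C = 1 - sum(t^3 - t)/(N^3 - N); 0 when all values are identical."""
    n = pooled.size
    if n < 2:
        return 1.0
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)


def _h_from_rank_sums(
    rank_sums: Sequence[float], sizes: Sequence[int], n: int
) -> float:
    grand = (n + 1) / 2.0
    h = 0.0
    for r, m in zip(rank_sums, sizes):
        h += m * (r / m - grand) ** 2
    return 12.0 / (n * (n + 1)) * h


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis outcome; NaN fields mean not computable."""

    h: float
    p: float

    @property
    def computable(self) -> bool:
        return not math.isnan(self.h)


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis rank test across k >= 2 groups.

    p is the upper tail of the chi-square distribution with k-1 degrees of
    freedom at the corrected statistic.  If every pooled value is identical
    the tie-correction denominator is zero and the result is not computable.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    c = _tie_correction(pooled)
    if c == 0.0:
        return KWResult(h=float("nan"), p=float("nan"))
    ranks = midranks(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0, *sizes])
    rank_sums = [
        float(ranks[bounds[i] : bounds[i + 1]].sum())
        for i in range(len(groups))
    ]
    h = _h_from_rank_sums(rank_sums, sizes, pooled.size) / c
    p = float(chi2.sf(h, df=len(groups) - 1))
    return KWResult(h=h, p=p)


def exact_kw_permutation(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    max_total_n: int = 12,
) -> float:
    """Exact permutation p-value for the two-group Kruskal-Wallis statistic.

    Enumerates every C(N, n_a) assignment of the pooled values to the two
    groups; p is the fraction of assignments whose tie-corrected H is at
    least the observed one (the observed assignment counts, so p > 0).
    Verification oracle only - reported p-values come from the chi-square
    approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n = a.size + b.size
    if n > max_total_n:
        raise ValueError(
            f"exact enumeration limited to N <= {max_total_n} "
            f"(got N = {n}); use kruskal_wallis for larger samples"
        )
    pooled = np.concatenate([a, b])
    c = _tie_correction(pooled)
    if c == 0.0:
        return float("nan")
    # Ranks are a property of the pooled values, so each reassignment only
    # changes which ranks land in group A.
    ranks = midranks(pooled)

    def h_of(idx_a: tuple[int, ...]) -> float:
        ra = float(ranks[list(idx_a)].sum())
        rb = float(ranks.sum()) - ra
        return _h_from_rank_sums([ra, rb], [a.size, b.size], n) / c

    observed = h_of(tuple(range(a.size)))
    tol = 1e-12
    hits = sum(
        1
        for idx in combinations(range(n), a.size)
        if h_of(idx) >= observed - tol
    )
    return hits / math.comb(n, a.size)


@dataclass
class TestResult:
    """One feature's Kruskal-Wallis outcome across the NYHA groups."""

    feature_name: str
    median_by_group: dict[NYHAGroup, float]
    n_by_group: dict[NYHAGroup, int]
    h_statistic: float
    p_value: float

    @property
    def computable(self) -> bool:
        return not math.isnan(self.h_statistic)

    @property
    def flag_05(self) -> bool:
        return self.computable and self.p_value <= 0.05

    @property
    def flag_01(self) -> bool:
        return self.computable and self.p_value <= 0.01


def run_battery(
    features: pd.DataFrame,
    grouping: Mapping[str, NYHAGroup] | pd.Series,
) -> list[TestResult]:
    """Kruskal-Wallis test of every feature column between the NYHA groups.

    ``features`` is indexed by patient_id with one numeric column per feature
    (demographic variables may be included as columns on the same footing, as
    the published battery does).  P-values are deliberately unadjusted for
    multiplicity; group medians use linear-interpolation quantiles.
    """
    grouping = pd.Series(dict(grouping))
    missing = features.index.difference(grouping.index)
    if len(missing):
        raise PreconditionError(
            f"patients without group assignment: {list(missing)[:5]}"
        )
    groups = [g for g in NYHAGroup]
    member_index = {
        g: features.index[grouping.loc[features.index] == g] for g in groups
    }
    for g, idx in member_index.items():
        if len(idx) < 2:
            raise PreconditionError(
                f"group {g.value} has {len(idx)} patients; need >= 2"
            )
    results = []
    for name in features.columns:
        col = features[name].astype(float)
        samples = [col.loc[member_index[g]].to_numpy() for g in groups]
        # Patients with a NaN feature value (not-computable statistic) drop
        # out of that feature's test only.
        samples = [s[~np.isnan(s)] for s in samples]
        if any(s.size < 2 for s in samples):
            kw = KWResult(h=float("nan"), p=float("nan"))
            medians = {
                g: (float(np.median(s)) if s.size else float("nan"))
                for g, s in zip(groups, samples)
            }
        else:
            kw = kruskal_wallis(samples)
            medians = {g: float(np.median(s)) for g, s in zip(groups, samples)}
        results.append(
            TestResult(
                feature_name=str(name),
                median_by_group=medians,
                n_by_group={g: int(s.size) for g, s in zip(groups, samples)},
                h_statistic=kw.h,
                p_value=kw.p,
            )
        )
    return results


def battery_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten TestResults to the tabular battery layout written to CSV."""
    rows = [
        {
            "feature": r.feature_name,
            "median_II_star": r.median_by_group[NYHAGroup.II_STAR],
            "median_III_star": r.median_by_group[NYHAGroup.III_STAR],
            "H": r.h_statistic,
            "p": r.p_value,
            "sig_05": r.flag_05,
            "sig_01": r.flag_01,
            "computable": r.computable,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
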