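"""Rank-based comparisons of plasma biomarkers across pathology groups.

Implements the Wilcoxon rank-sum test (exact enumeration for small
samples, tie-corrected normal approximation with continuity correction
otherwise), the Hodges-Lehmann shift estimator with rank-sum-inversion
or bootstrap confidence intervals, the Kruskal-Wallis omnibus test,
Bonferroni adjustment and 2x2 chi-square tests, and ties them together
into the control / A-/T- / A+/T- / A+/T+ comparison of one biomarker.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import COMPARISON_GROUPS, AnalysisTable


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float
    degrees_of_freedom: int | None
    p_value: float
    tie_correction_applied: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    rank_sum_statistic: float
    raw_p: float
    adjusted_p: float
    hl_shift: float
    hl_ci_low: float
    hl_ci_high: float
    ci_level: float


@dataclass
class GroupComparisonReport:
    biomarker: str
    omnibus: OmnibusResult
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    family_size: int = 0


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y using midranks (ties count 1/2)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def _exact_u_distribution(pooled: np.ndarray, n_a: int) -> np.ndarray:
    """U statistic of every C(n, n_a) group assignment of the pooled values."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    return np.array(
        [sum(ranks[list(idx)]) - offset for idx in itertools.combinations(range(n), n_a)]
    )


def wilcoxon_rank_sum(x, y, mode: str = "normal") -> OmnibusResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact`` enumerates the full permutation distribution of the U
    statistic (feasible for n_a + n_b <= 20, ties handled via midranks);
    ``normal`` uses the tie-corrected normal approximation with
    continuity correction.  If every observation across both samples is
    identical the data carry no ordering information: p = 1 with the
    degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be non-empty")
    n_a, n_b = len(x), len(y)
    u = _mann_whitney_u(x, y)

    if np.all(np.concatenate([x, y]) == x[0]):
        return OmnibusResult(u, None, 1.0, tie_correction_applied=True, degenerate=True)

    if mode == "exact":
        if n_a + n_b > 20:
            raise ValueError("wilcoxon_rank_sum: exact mode requires n_a + n_b <= 20")
        dist = _exact_u_distribution(np.concatenate([x, y]), n_a)
        center = n_a * n_b / 2.0
        # the permutation distribution of U is symmetric about n_a*n_b/2
        p = float(np.mean(np.abs(dist - center) >= abs(u - center) - 1e-12))
        return OmnibusResult(u, None, min(1.0, p))
    if mode != "normal":
        raise ValueError(f"wilcoxon_rank_sum: unknown mode {mode!r}")

    n = n_a + n_b
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    has_ties = tie_term > 0
    if var <= 0:
        return OmnibusResult(u, None, 1.0, tie_correction_applied=bool(has_ties), degenerate=True)
    mean = n_a * n_b / 2.0
    z = (abs(u - mean) - 0.5) / math.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return OmnibusResult(u, None, p, tie_correction_applied=bool(has_ties))


def _exact_lower_critical(n_a: int, n_b: int, alpha_half: float) -> int:
    """Largest k with P(U <= k) <= alpha/2 under the tie-free exact null."""
    # distribution of U over rank assignments; tie-free so integer-valued
    dist = _exact_u_distribution(np.arange(n_a + n_b, dtype=float), n_a)
    values, counts = np.unique(dist, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    ok = values[cdf <= alpha_half + 1e-12]
    return int(ok[-1]) if len(ok) else -1


def hodges_lehmann_shift(
    x,
    y,
    ci_level: float = 0.95,
    method: str = "inversion",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Hodges-Lehmann location shift of x relative to y, with CI.

    The point estimate is the median of all n_a * n_b pairwise
    differences x_i - y_j.  ``inversion`` derives the CI from the
    ordered pairwise differences at Wilcoxon rank-sum critical values
    (exact null distribution for n_a + n_b <= 20, normal approximation
    otherwise); ``bootstrap`` uses a seeded percentile interval over
    participant resamples, the recommended fallback when heavy ties make
    inversion conservative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("hodges_lehmann_shift: both samples must be non-empty")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    estimate = float(np.median(diffs))
    m = len(diffs)
    alpha = 1.0 - ci_level

    if method == "inversion":
        n_a, n_b = len(x), len(y)
        if n_a + n_b <= 20:
            k = _exact_lower_critical(n_a, n_b, alpha / 2.0)
        else:
            z = stats.norm.ppf(1.0 - alpha / 2.0)
            k = int(math.floor(m / 2.0 - z * math.sqrt(n_a * n_b * (n_a + n_b + 1) / 12.0)))
        if k < 0:
            # sample too small for the requested level: widest possible interval
            return estimate, float(diffs[0]), float(diffs[-1])
        # CI = (D_(k+1), D_(m-k)) in 1-based order statistics
        return estimate, float(diffs[k]), float(diffs[m - k - 1])
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            xb = x[rng.integers(0, len(x), len(x))]
            yb = y[rng.integers(0, len(y), len(y))]
            reps[i] = np.median(np.subtract.outer(xb, yb))
        lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
        return estimate, float(lo), float(hi)
    raise ValueError(f"hodges_lehmann_shift: unknown method {method!r}")


def kruskal_wallis(groups: Sequence) -> OmnibusResult:
    """Kruskal-Wallis H test with tie correction (chi-square, k-1 df)."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(len(g) == 0 for g in samples):
        raise ValueError("kruskal_wallis: need >= 2 non-empty groups")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return OmnibusResult(0.0, df, 1.0, tie_correction_applied=True, degenerate=True)
    h, p = stats.kruskal(*samples)
    return OmnibusResult(float(h), df, float(p), tie_correction_applied=bool(has_ties))


def bonferroni_adjust(p_values: Sequence[float], family_size: int | None = None) -> list[float]:
    """Multiply each p by the family size, capping at 1 (order-preserving)."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("bonferroni_adjust: p-values must be in [0, 1]")
    m = family_size if family_size is not None else len(ps)
    return [min(1.0, p * m) for p in ps]


def chi_square_2x2(table, correction: bool = False) -> OmnibusResult:
    """Pearson chi-square on a 2x2 count table, optional Yates correction."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("chi_square_2x2: table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("chi_square_2x2: counts must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi_square_2x2: zero margin")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=correction)
    return OmnibusResult(float(stat), int(dof), float(p))


def compare_by_pathology_group(
    analysis_table: AnalysisTable,
    biomarker: str,
    groups: Sequence[str] = COMPARISON_GROUPS,
    ci_level: float = 0.95,
    hl_method: str = "inversion",
) -> GroupComparisonReport:
    """Omnibus Kruskal-Wallis plus all pairwise Wilcoxon tests for one
    biomarker across the pathology groups.

    Bonferroni adjustment uses the full pairwise family actually tested;
    any group with fewer than 2 observations has its pairs skipped and
    logged rather than silently dropped.
    """
    data = analysis_table.data if isinstance(analysis_table, AnalysisTable) else analysis_table
    if biomarker not in data.columns:
        raise ValueError(f"compare_by_pathology_group: no column {biomarker!r}")
    samples = {}
    skipped: list[dict] = []
    for label in groups:
        values = data.loc[data["at_group"] == label, biomarker].dropna().to_numpy()
        if len(values) < 2:
            skipped.append({"group": label, "n": int(len(values)), "reason": "n < 2"})
        else:
            samples[label] = values

    if len(samples) < 2:
        raise ValueError("compare_by_pathology_group: fewer than 2 usable groups")
    omnibus = kruskal_wallis(list(samples.values()))

    pairs = list(itertools.combinations(samples.keys(), 2))
    family = len(pairs)
    raw = []
    for a, b in pairs:
        raw.append(wilcoxon_rank_sum(samples[a], samples[b], mode="normal").p_value)
    adjusted = bonferroni_adjust(raw, family_size=family)

    comparisons = []
    for (a, b), p_raw, p_adj in zip(pairs, raw, adjusted):
        shift, lo, hi = hodges_lehmann_shift(
            samples[a], samples[b], ci_level=ci_level, method=hl_method
        )
        comparisons.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                n_a=len(samples[a]),
                n_b=len(samples[b]),
                rank_sum_statistic=_mann_whitney_u(samples[a], samples[b]),
                raw_p=p_raw,
                adjusted_p=p_adj,
                hl_shift=shift,
                hl_ci_low=lo,
                hl_ci_high=hi,
                ci_level=ci_level,
            )
        )
    return GroupComparisonReport(
        biomarker=biomarker,
        omnibus=omnibus,
        pairwise=comparisons,
        skipped=skipped,
        family_size=family,
    )
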