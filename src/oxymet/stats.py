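"""Group-level statistics for the imaging cohort.

Nonparametric group comparison (Kruskal–Wallis omnibus with pairwise
rank-sum post-hocs under Bonferroni correction), Shapiro–Wilk normality
screening, Pearson correlation, coefficients of variation, a normal-
approximation two-sample power calculation, and per-day disease-score
trajectory divergence.

Conventions: sample SD (n−1) throughout; two-sided tests throughout;
missing values dropped pairwise for correlations and listwise within a
metric for group tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "GroupComparison",
    "NormalityScreen",
    "PearsonResult",
    "TrajectoryDivergence",
    "normality_screen",
    "kruskal_wallis_pairwise",
    "pearson_corr",
    "coefficient_of_variation",
    "sample_size_power",
    "trajectory_divergence",
]


class GroupSummary(NamedTuple):
    group: str
    mean: float
    sd: float
    n: int
    cv_pct: float


class PairwiseComparison(NamedTuple):
    pair: tuple[str, str]
    raw_p: float
    bonferroni_p: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # Kruskal–Wallis H
    omnibus_p: float
    pairwise: tuple[PairwiseComparison, ...]
    summaries: tuple[GroupSummary, ...]


class NormalityScreen(NamedTuple):
    p_values: dict[str, float]
    degenerate: dict[str, bool]
    recommendation: str  # "parametric" | "nonparametric"


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


class TrajectoryDivergence(NamedTuple):
    first_significant_day: float | None
    days: tuple[float, ...]
    raw_p: tuple[float, ...]
    corrected_p: tuple[float, ...]
    n_per_day: tuple[tuple[int, int], ...]


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def normality_screen(values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05) -> NormalityScreen:
    """Shapiro–Wilk screen per group; recommends nonparametric testing
    when any group rejects normality at ``alpha``.

    Constant (zero-variance) groups are reported as degenerate with a
    NaN p-value rather than raising.
    """
    p_values: dict[str, float] = {}
    degenerate: dict[str, bool] = {}
    for name, vals in values_by_group.items():
        arr = _clean(vals)
        if arr.size < 3:
            raise ValueError(f"group {name!r} needs n >= 3 for a normality screen")
        if np.ptp(arr) == 0:
            p_values[name] = math.nan
            degenerate[name] = True
            continue
        p_values[name] = float(sps.shapiro(arr).pvalue)
        degenerate[name] = False
    reject = any(
        (not degenerate[g]) and p_values[g] < alpha for g in p_values
    ) or any(degenerate.values())
    return NormalityScreen(p_values, degenerate, "nonparametric" if reject else "parametric")


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation, 100 · SD(n−1) / mean (%)."""
    arr = _clean(values)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * np.std(arr, ddof=1) / mean)


def kruskal_wallis_pairwise(
    values_by_group: Mapping[str, Sequence[float]], posthoc: str = "ranksum"
) -> GroupComparison:
    """Kruskal–Wallis omnibus test with Bonferroni-corrected pairwise post-hocs.

    ``posthoc='ranksum'`` (default) runs two-sided Mann–Whitney tests on
    each group pair; ``posthoc='dunn'`` uses Dunn's z-tests on the pooled
    ranks.  Either way raw p-values are multiplied by the number of
    pairs and capped at 1.
    """
    groups = {name: _clean(vals) for name, vals in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    names = list(groups)
    arrays = [groups[n] for n in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        h, omnibus_p = 0.0, 1.0
    else:
        h, omnibus_p = sps.kruskal(*arrays)
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    pairwise = []
    if posthoc == "dunn":
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        splits = np.cumsum([a.size for a in arrays])[:-1]
        rank_groups = dict(zip(names, np.split(ranks, splits)))
        n_tot = pooled.size
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
        for a, b in pairs:
            ra, rb = rank_groups[a], rank_groups[b]
            se = math.sqrt(
                (n_tot * (n_tot + 1) / 12.0 - tie_term) * (1.0 / ra.size + 1.0 / rb.size)
            )
            z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
            raw = 2.0 * sps.norm.sf(abs(z))
            pairwise.append(PairwiseComparison((a, b), float(raw), float(min(1.0, raw * n_pairs))))
    elif posthoc == "ranksum":
        for a, b in pairs:
            if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
                raw = 1.0
            else:
                raw = float(sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
            pairwise.append(PairwiseComparison((a, b), raw, float(min(1.0, raw * n_pairs))))
    else:
        raise ValueError("posthoc must be 'ranksum' or 'dunn'")
    summaries = tuple(
        GroupSummary(
            name,
            float(arr.mean()),
            float(np.std(arr, ddof=1)),
            int(arr.size),
            float(100.0 * np.std(arr, ddof=1) / arr.mean()) if arr.mean() != 0 else math.nan,
        )
        for name, arr in groups.items()
    )
    return GroupComparison(float(h), float(omnibus_p), tuple(pairwise), summaries)


def pearson_corr(x, y) -> PearsonResult:
    """Pearson correlation with a two-sided t-transform p (n−2 df).

    Pairs with a missing value in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), int(x.size))


def sample_size_power(delta: float, sd: float, alpha: float = 0.05, power: float = 0.95) -> int:
    """Two-sample normal-approximation sample size per group.

    n = ceil( 2 · (z_{1−α/2} + z_{power})² · sd² / delta² )
    """
    if delta <= 0 or sd <= 0 or alpha <= 0 or not 0 < power < 1:
        raise ValueError("delta, sd, alpha must be positive and power in (0, 1)")
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    z_power = sps.norm.ppf(power)
    n = 2.0 * (z_alpha + z_power) ** 2 * sd**2 / delta**2
    return int(math.ceil(n))


def trajectory_divergence(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "per_day",
) -> TrajectoryDivergence:
    """First day on which two groups' daily disease scores diverge.

    ``scores_a``/``scores_b`` are day-indexed frames (one column per
    animal; NaN marks attrition).  The default method compares the
    groups day by day with two-sided rank-sum tests, Bonferroni-
    corrected across the number of shared days; ``method='rm_anova'``
    instead fits a mixed-design repeated-measures ANOVA (via pingouin)
    on complete cases and then uses the same per-day post-hocs to locate
    the earliest divergence.  Returns the earliest day whose corrected
    p < ``alpha`` (None if none) with the full per-day p list.
    """
    days = sorted(set(scores_a.index) & set(scores_b.index))
    if len(days) < 2:
        raise ValueError("need at least two shared days")
    if method == "rm_anova":
        _mixed_rm_anova(scores_a, scores_b, days)  # omnibus contract; divergence below
    elif method != "per_day":
        raise ValueError("method must be 'per_day' or 'rm_anova'")
    raw_ps, ns = [], []
    for day in days:
        a = _clean(scores_a.loc[day].to_numpy())
        b = _clean(scores_b.loc[day].to_numpy())
        ns.append((int(a.size), int(b.size)))
        if a.size == 0 or b.size == 0:
            raw_ps.append(math.nan)
        elif np.ptp(np.concatenate([a, b])) == 0:
            raw_ps.append(1.0)
        else:
            raw_ps.append(
                float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            )
    m = len(days)
    corrected = [min(1.0, p * m) if np.isfinite(p) else math.nan for p in raw_ps]
    first = None
    for day, p in zip(days, corrected):
        if np.isfinite(p) and p < alpha:
            first = day
            break
    return TrajectoryDivergence(
        first, tuple(float(d) for d in days), tuple(raw_ps), tuple(corrected), tuple(ns)
    )


def _mixed_rm_anova(scores_a: pd.DataFrame, scores_b: pd.DataFrame, days) -> None:
    """Mixed-design RM ANOVA omnibus on complete cases (contract only)."""
    import pingouin as pg  # heavy import kept local

    records = []
    for group, frame in (("a", scores_a), ("b", scores_b)):
        sub = frame.loc[days].dropna(axis=1)
        for col in sub.columns:
            for day in days:
                records.append(
                    {"subject": f"{group}:{col}", "group": group, "day": day,
                     "score": float(sub.loc[day, col])}
                )
    df = pd.DataFrame(records)
    if df["subject"].nunique() >= 4:
        pg.mixed_anova(data=df, dv="score", within="day", between="group", subject="subject")
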