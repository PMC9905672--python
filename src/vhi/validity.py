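"""Validity-assessment statistics for the health index.

Criterion validity: Pearson correlation of the index with plasma biomarkers
(insulin, TNF-alpha) that are expected to correlate negatively with vascular
health.  Group differences: one-way ANOVA followed by the Newman-Keuls
stepwise studentized-range post hoc procedure (the significance markers used
throughout the cohort tables).  Discriminant validity: the index must order
healthy (LZR), diseased (OZR) and deliberately worsened (OZR+L-NAME) cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError
from .scoring import CohortSummary, VHIResult

__all__ = [
    "CorrelationReport",
    "PosthocReport",
    "pearson",
    "one_way_anova",
    "newman_keuls",
    "criterion_validity",
    "discriminant_check",
]

DEFAULT_ALPHA = 0.05


@lru_cache(maxsize=512)
def studentized_range_crit(alpha: float, span: int, df: int) -> float:
    """Upper critical value q(alpha, span, df) of the studentized range.

    Computed numerically from the range distribution; cached because post hoc
    sweeps and null simulations reuse a handful of (span, df) combinations.
    """
    return float(stats.studentized_range.ppf(1.0 - alpha, span, df))


@dataclass(frozen=True)
class CorrelationReport:
    variable_pair: tuple
    n: int
    r: float
    p_value: float


@dataclass(frozen=True)
class PosthocReport:
    """ANOVA + Newman-Keuls pairwise decisions.

    ``pairs`` holds one entry per unordered group pair:
    (label_a, label_b, significant-at-alpha).
    """

    group_labels: tuple
    group_means: tuple
    anova_F: float
    anova_p: float
    alpha: float
    pairs: tuple

    def significant_pairs(self) -> set:
        return {frozenset((a, b)) for a, b, sig in self.pairs if sig}


def pearson(x: Sequence[float], y: Sequence[float], labels=("x", "y")) -> CorrelationReport:
    """Product-moment correlation with a two-sided t-based p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise InvalidInputError(f"need >= 3 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationReport(
        variable_pair=tuple(labels), n=int(x.size),
        r=float(res.statistic), p_value=float(res.pvalue),
    )


def _validate_groups(groups: Sequence[Sequence[float]]):
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")
    arrs = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise InvalidInputError(f"group {i} must have >= 2 values")
        if not np.all(np.isfinite(a)):
            raise InvalidInputError(f"group {i} contains non-finite values")
        arrs.append(a)
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical between/within mean-square F ratio with its p-value.

    Sums of squares are computed directly so the degenerate all-identical
    case can be given the conventional answer F = 0, p = 1 instead of NaN.
    """
    arrs = _validate_groups(groups)
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def newman_keuls(
    groups: Sequence[Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
    labels: Optional[Sequence[str]] = None,
) -> PosthocReport:
    """Stepwise Newman-Keuls multiple comparison of group means.

    Means are ordered and compared with studentized-range statistics whose
    critical value q(alpha, span, df_within) depends on the number of ordered
    means spanned; the standard error uses the pooled within-group mean
    square and, for unequal group sizes, the harmonic mean of the pair's
    sizes.  The containment rule is enforced: once a span fails to reach
    significance, every pair inside it is declared non-significant without
    testing, so a pair inside a non-rejected stretch is never marked
    significant.
    """
    if not (0 < alpha < 1):
        raise InvalidInputError("alpha must be in (0, 1)")
    arrs = _validate_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    elif len(labels) != k:
        raise InvalidInputError("labels length must match the number of groups")

    f_stat, p_val = one_way_anova(arrs)
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    df_w = int(ns.sum() - k)
    msw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs) / df_w

    order = np.argsort(means, kind="stable")
    sorted_means = means[order]
    sorted_ns = ns[order]

    # decisions[(i, j)] over sorted positions i < j
    decisions: dict[tuple[int, int], bool] = {}

    def crit(span: int) -> float:
        return studentized_range_crit(alpha, span, df_w)

    def mark_inside_ns(i: int, j: int):
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                decisions.setdefault((a, b), False)

    def test(i: int, j: int):
        if j <= i or (i, j) in decisions:
            return
        if msw == 0:
            # no within-group variation: any mean difference is a rejection
            sig = sorted_means[j] > sorted_means[i]
        else:
            n_h = 2.0 / (1.0 / sorted_ns[i] + 1.0 / sorted_ns[j])
            q = (sorted_means[j] - sorted_means[i]) / math.sqrt(msw / n_h)
            sig = q > crit(j - i + 1)
        if sig:
            decisions[(i, j)] = True
            test(i, j - 1)
            test(i + 1, j)
        else:
            mark_inside_ns(i, j)

    test(0, k - 1)
    # pairs never reached (possible only if the full range itself was marked) default to NS
    mark_inside_ns(0, k - 1)

    pairs = []
    pos_of = {int(g): p for p, g in enumerate(order)}
    for a in range(k):
        for b in range(a + 1, k):
            i, j = sorted((pos_of[a], pos_of[b]))
            pairs.append((labels[a], labels[b], decisions[(i, j)]))
    return PosthocReport(
        group_labels=tuple(labels), group_means=tuple(float(m) for m in means),
        anova_F=f_stat, anova_p=p_val, alpha=alpha, pairs=tuple(pairs),
    )


def criterion_validity(
    results: Sequence,
    biomarker: Sequence[float],
    threshold: float = -0.5,
    biomarker_name: str = "biomarker",
) -> tuple[CorrelationReport, bool]:
    """Correlate the index with a biomarker expected to track disease severity.

    ``results`` may be VHIResult objects or plain index values, matched
    one-to-one with ``biomarker``.  The verdict passes when the correlation
    is at least as negative as ``threshold`` (r <= threshold).
    """
    if threshold > 0:
        raise InvalidInputError("threshold must be <= 0 (a negative correlation is expected)")
    vhi = [r.vhi if isinstance(r, VHIResult) else float(r) for r in results]
    if len(vhi) != len(biomarker):
        raise InvalidInputError("results and biomarker must be matched one-to-one")
    if len(vhi) < 3:
        raise InvalidInputError("need >= 3 matched animals")
    report = pearson(vhi, biomarker, labels=("vhi", biomarker_name))
    return report, bool(report.r <= threshold)


def discriminant_check(summaries: Sequence[CohortSummary]) -> bool:
    """Ordering check LZR > OZR > OZR+LNM on cohort mean index at one stratum.

    The L-NAME-treated cohort, with nitric oxide bioavailability removed,
    must score below untreated OZR, which must score below healthy LZR.
    """
    by_group = {}
    for s in summaries:
        by_group[s.group] = s
    for g in ("LZR", "OZR", "OZR+LNM"):
        if g not in by_group:
            raise InvalidInputError(f"missing group {g} for discriminant check")
    strata = {(s.age_wk, s.bed) for s in by_group.values()}
    if len(strata) != 1:
        raise InvalidInputError("discriminant check expects one (age, bed) stratum")
    return bool(
        by_group["LZR"].vhi_mean > by_group["OZR"].vhi_mean > by_group["OZR+LNM"].vhi_mean
    )
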