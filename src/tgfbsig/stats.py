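"""Cohort statistics: correlation, group comparison, association tests,
Kaplan-Meier estimation and log-rank tests with Bonferroni correction.

Spearman correlation, Fisher's exact test, the chi-square test and the
large-sample Mann-Whitney branch delegate to scipy.stats; small-sample exact
p-values (Spearman n <= 8, Mann-Whitney with both groups <= 8) are computed
by full enumeration with average-rank tie handling.  The Kaplan-Meier
product-limit estimator and the unweighted Mantel-Haenszel log-rank statistic
are implemented directly since the censoring and tie conventions are part of
the contract (censored observations at an event time remain at risk for that
event).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, GroupingError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class AssociationResult:
    test_name: str
    p_value: float
    statistic: Optional[float] = None
    table_shape: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class KMCurve:
    """Product-limit curve: survival probability after each distinct event
    time, with the size of the risk set at that time."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond t (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    dof: int
    p_value: float
    p_adjusted: Optional[float] = None
    groups: Optional[Tuple[str, str]] = None


def _check_pair(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    return x, y


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t-approximation for n > 8 and an exact two-sided
    permutation enumeration for n <= 8.
    """
    x, y = _check_pair(x, y)
    n = x.size
    if n < 3:
        raise ValidationError("need >= 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for a constant vector")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= observed - 1e-12
            total += 1
        p = count / total
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, n=n, p_value=min(1.0, p))


def _mannwhitney_u(ranks: np.ndarray, idx1: Sequence[int], n1: int) -> float:
    return float(ranks[list(idx1)].sum() - n1 * (n1 + 1) / 2.0)


def compare_score_by_group(scores: Sequence[float], group_labels: Sequence[int],
                           method: str = "mannwhitney") -> AssociationResult:
    """Two-sided two-group comparison of scores (default Mann-Whitney U).

    Exact enumeration of all group labelings when both groups have <= 8
    members (ties handled by average ranks); normal approximation with
    continuity correction otherwise.  ``method="welch"`` switches to the
    Welch t-test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise GroupingError(f"need exactly 2 groups, got {groups.size}")
    g1 = scores[labels == groups[0]]
    g2 = scores[labels == groups[1]]
    if g1.size == 0 or g2.size == 0:
        raise GroupingError("empty group")
    if method == "welch":
        t, p = sps.ttest_ind(g1, g2, equal_var=False)
        return AssociationResult("welch_t", float(p), statistic=float(t))
    if method != "mannwhitney":
        raise ValidationError(f"unknown method {method!r}")

    n1, n2 = g1.size, g2.size
    ranks = sps.rankdata(np.concatenate([g1, g2]))
    u_obs = _mannwhitney_u(ranks, range(n1), n1)
    if n1 <= 8 and n2 <= 8:
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = _mannwhitney_u(ranks, idx, n1)
            count += abs(u - mu) >= dev - 1e-12
            total += 1
        p = count / total
    else:
        p = float(
            sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic",
                             use_continuity=True).pvalue
        )
    return AssociationResult("mann_whitney", min(1.0, p), statistic=u_obs)


def fisher_exact_2x2(table) -> AssociationResult:
    """Two-sided Fisher's exact test (sum of hypergeometric probabilities of
    all tables with fixed margins no more probable than the observed one)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("need a 2x2 table of non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin in 2x2 table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return AssociationResult("fisher_exact", float(p), statistic=float(odds),
                             table_shape=(2, 2))


def chi_square_test(table, yates: bool = False) -> AssociationResult:
    """Pearson chi-square test of independence on an r x c table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValidationError("need an r x c table of non-negative counts")
    total = table.sum()
    if total == 0:
        raise DegenerateTableError("empty table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        raise DegenerateTableError("zero expected count; use fisher_exact_2x2")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=yates)
    return AssociationResult("chi_square", float(p), statistic=float(stat),
                             table_shape=table.shape)


def _check_survival(times, events) -> Tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty survival input")
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if (times < 0).any():
        raise ValidationError("times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0 or 1")
    return times, events


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    The risk set at time t contains every subject with observed time >= t, so
    a censored observation at an event time is still at risk for that event.
    """
    times, events = _check_survival(times, events)
    event_times = np.unique(times[events == 1])
    probs = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        probs[i] = s
        at_risk[i] = n_t
    return KMCurve(event_times=event_times, survival_probs=probs, at_risk=at_risk)


def logrank_test(times: Sequence[float], events: Sequence[int],
                 group_labels: Sequence) -> LogRankResult:
    """Unweighted Mantel-Haenszel two-group log-rank test.

    statistic = (sum(O1 - E1))^2 / sum(V) over distinct pooled event times,
    with the hypergeometric variance at each time; p from chi-square(1).
    """
    times, events = _check_survival(times, events)
    labels = np.asarray(group_labels)
    if labels.shape != times.shape:
        raise ValidationError("group labels must match times")
    groups = np.unique(labels)
    if groups.size != 2:
        raise GroupingError(f"need exactly 2 groups, got {groups.size}")
    in1 = labels == groups[0]
    if in1.all() or not in1.any():
        raise GroupingError("empty group")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        stat = 0.0
    else:
        stat = o_minus_e**2 / var
    p = float(sps.chi2.sf(stat, df=1)) if var > 0 else 1.0
    return LogRankResult(statistic=float(stat), dof=1, p_value=p,
                         groups=(str(groups[0]), str(groups[1])))


def pairwise_logrank_bonferroni(times: Sequence[float], events: Sequence[int],
                                strata: Sequence) -> List[LogRankResult]:
    """All pairwise two-group log-rank tests across k strata with Bonferroni
    adjustment by the k(k-1)/2 comparisons actually run (capped at 1)."""
    times, events = _check_survival(times, events)
    strata = np.asarray(strata)
    if strata.shape != times.shape:
        raise ValidationError("strata must match times")
    levels = [str(v) for v in np.unique(strata)]
    if len(levels) < 2:
        raise GroupingError("need >= 2 strata")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        mask = np.isin(strata.astype(str), (a, b))
        res = logrank_test(times[mask], events[mask], strata.astype(str)[mask])
        results.append(
            LogRankResult(
                statistic=res.statistic,
                dof=res.dof,
                p_value=res.p_value,
                p_adjusted=min(1.0, res.p_value * m),
                groups=(a, b),
            )
        )
    return results
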