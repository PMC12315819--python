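"""Cohort-level biomarker statistics.

The evaluation protocol for per-sample aggregate counts: Student's t-test
for two-group comparisons (equal-variance by default, Welch optional),
one-way ANOVA with Tukey HSD for three or more groups, ROC/AUC with a
stratified percentile-bootstrap confidence interval for diagnostic
performance, and Spearman rank correlation against clinical covariates
(HbA1c, UPDRS-III and similar).

AUC is the normalized Mann-Whitney statistic with half-credit for ties —
the probability that a random patient scores above a random control.
Patients are coded positive and the AUC is never flipped; a value below 0.5
is reported as-is.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from .types import CorrelationResult, ParameterError, RocResult

__all__ = [
    "compare_two_groups",
    "compare_multi",
    "roc",
    "spearman_corr",
]


def compare_two_groups(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_multi(groups) -> tuple[float, float, dict[tuple[int, int], float]]:
    """One-way ANOVA with Tukey HSD post-hoc.

    Returns (F, p, tukey_pairs) where tukey_pairs maps a group-index pair
    (i, j), i < j, to its Tukey-adjusted p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ParameterError(
            "compare_multi needs >= 3 groups; use compare_two_groups for two")
    if any(len(g) < 2 for g in groups):
        raise ParameterError("each group needs at least 2 observations")
    if all(np.var(g, ddof=1) == 0 for g in groups) and \
            len({float(np.mean(g)) for g in groups}) == 1:
        F, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*groups)
        F, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    tukey = stats.tukey_hsd(*groups)
    pairs = {(i, j): float(tukey.pvalue[i, j])
             for i, j in itertools.combinations(range(len(groups)), 2)}
    return F, p, pairs


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc(scores, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """AUC with a stratified percentile-bootstrap 95% CI.

    Positives and negatives are resampled separately (both classes always
    present in a replicate); the CI is the 2.5/97.5 percentile of the
    bootstrap AUC distribution.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ParameterError("labels must be binary 0/1")
    point = auc_mann_whitney(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    lab = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    for i in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots[i] = auc_mann_whitney(np.concatenate([bp, bn]), lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return RocResult(auc=point, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman_corr(x, y, exact_n_max: int = 9) -> CorrelationResult:
    """Spearman rank correlation on mid-ranks.

    The p-value is exact by full permutation of one rank vector for
    n <= ``exact_n_max`` and a t-approximation (df = n - 2) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ParameterError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _spearman_r(rx, ry)
    if n <= exact_n_max:
        # exact two-sided permutation p over all n! orderings of y's ranks
        rxc = rx - rx.mean()
        norm = np.sqrt(np.sum(rxc ** 2) * np.sum((ry - ry.mean()) ** 2))
        count = 0
        total = math.factorial(n)
        target = abs(r) - 1e-12
        for perm in itertools.permutations(ry):
            rp = np.dot(rxc, perm) / norm
            if abs(rp) >= target:
                count += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p_value=min(max(p, 0.0), 1.0), n=n)
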