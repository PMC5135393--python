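"""Group summaries and normality-routed two-group comparisons.

Groups are summarized as mean ± SEM with a two-sided 95% confidence
interval.  Two CI rules are first-class: ``normal_z`` (mean ± 1.96·SEM)
and ``student_t`` (mean ± t(0.975, n−1)·SEM) — published laminar-position
intervals are consistent with one rule in some groups and the other in
others, so the choice is explicit per call rather than hidden.

Two-group comparisons follow the reporting convention of the field:
Shapiro–Wilk normality on each group, then an unpaired two-tailed t-test
if both pass, otherwise a two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .datatypes import GroupSummary, TestResult

__all__ = ["confidence_interval", "summarize_group", "compare_groups"]


def confidence_interval(
    mean: float,
    sem: float,
    n: int,
    level: float = 0.95,
    method: str = "normal_z",
) -> tuple[float, float]:
    """Two-sided confidence interval from a reported mean, SEM and n.

    ``normal_z`` uses the standard-normal quantile (1.96 at 95%);
    ``student_t`` uses the Student-t quantile at n − 1 degrees of freedom.
    """
    if sem < 0:
        raise ValueError("sem must be non-negative")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    q_tail = 0.5 + level / 2.0
    if method == "normal_z":
        q = sps.norm.ppf(q_tail)
    elif method == "student_t":
        if n < 2:
            raise ValueError("student_t interval needs n >= 2")
        q = sps.t.ppf(q_tail, df=n - 1)
    else:
        raise ValueError("method must be 'normal_z' or 'student_t'")
    half = q * sem
    return float(mean - half), float(mean + half)


def summarize_group(
    values, level: float = 0.95, method: str = "normal_z"
) -> GroupSummary:
    """Mean, SEM (sd/sqrt(n), sd with n−1 denominator) and CI for one group.

    A single-observation group gets SEM 0 and a degenerate interval at the
    mean (the sample SD is undefined at n = 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    n = int(arr.size)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    if n == 1:
        lo = hi = mean
    else:
        lo, hi = confidence_interval(mean, sem, n, level=level, method=method)
    return GroupSummary(
        mean=mean, sem=sem, n=n, ci_low=lo, ci_high=hi, ci_method=method, level=level
    )


def _mann_whitney_method(a: np.ndarray, b: np.ndarray) -> str:
    """Exact distribution for small samples without ties, else asymptotic.

    scipy's exact Mann-Whitney distribution does not correct for ties, so
    tied data always routes to the continuity-corrected normal
    approximation.
    """
    pooled = np.concatenate([a, b])
    if pooled.size <= 20 and np.unique(pooled).size == pooled.size:
        return "exact"
    return "asymptotic"


def compare_groups(
    a,
    b,
    alpha_normality: float = 0.05,
    equal_var: bool = True,
) -> TestResult:
    """Normality-routed unpaired two-group comparison.

    Shapiro–Wilk is run on each group; if both p-values exceed
    ``alpha_normality`` an unpaired two-tailed t-test (classical
    equal-variance by default, Welch with ``equal_var=False``) is used,
    otherwise a two-sided Mann–Whitney U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    # Shapiro-Wilk degenerates on constant data; a constant group is
    # trivially non-normal for routing purposes.
    norm_p_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
    norm_p_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
    if norm_p_a > alpha_normality and norm_p_b > alpha_normality:
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative="two-sided")
        test_used = "unpaired_t"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method=_mann_whitney_method(a, b)
        )
        test_used = "mann_whitney"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test_used=test_used,
        normality_p_a=norm_p_a,
        normality_p_b=norm_p_b,
        n_a=int(a.size),
        n_b=int(b.size),
    )
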