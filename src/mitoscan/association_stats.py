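"""Contingency tests, odds ratios, and summary-statistic comparisons.

The per-site association machinery (2x2 chi-square / Fisher with odds ratio
and Woolf confidence interval), the r x 2 lineage-distribution chi-square,
and the summary-level Student's t / Cohen's d comparisons used for cohort
covariates such as age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateTableError(ValueError):
    """A contingency table has an empty row or column margin."""


@dataclass
class ContingencyResult:
    """2x2 test outcome.

    The table layout is (a, b) = group-1 allele-1/allele-2 counts and
    (c, d) = group-2 allele-1/allele-2 counts.
    """

    a: int
    b: int
    c: int
    d: int
    statistic: float
    p_value: float
    test: str  # "chi_square" | "fisher_exact"
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    ci_method: str = "woolf"
    continuity_corrected: bool = False


@dataclass
class SummaryComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: int
    p_value: float
    cohens_d: float
    d_method: str = "rms_sd"
    kind: str = "student"


def _check_margins(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(f"zero margin in table ({a},{b},{c},{d})")


def odds_ratio_ci(
    a: int,
    b: int,
    c: int,
    d: int,
    level: float = 0.95,
    correction: str = "haldane",
    method: str = "woolf",
) -> tuple[float, float, float]:
    """Odds ratio ``ad/bc`` with a confidence interval.

    ``method="woolf"`` (default): log-scale normal interval
    ``exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d))``.  ``method="exact"``: the
    exact conditional (hypergeometric) interval, with the sample odds ratio
    still reported as the point estimate.  When any cell is zero the
    Haldane–Anscombe +0.5 correction is applied to every cell (default); with
    ``correction=None`` a zero ``b*c`` yields an infinite OR with an open
    upper bound.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if method == "exact":
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        if b * c == 0:
            or_point = math.inf if c == 0 or b == 0 else (a * d) / (b * c)
        else:
            or_point = (a * d) / (b * c)
        return float(or_point), float(ci.low), float(ci.high)

    z = stats.norm.ppf(0.5 + level / 2.0)
    if min(a, b, c, d) == 0:
        if correction == "haldane":
            aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        else:
            # uncorrected zero cell: degenerate point estimate, open interval
            or_point = math.inf if b * c == 0 else (a * d) / (b * c)
            return or_point, 0.0, math.inf
    else:
        aa, bb, cc, dd = a, b, c, d
    or_point = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return (
        float(or_point),
        float(or_point * math.exp(-z * se)),
        float(or_point * math.exp(z * se)),
    )


def two_by_two_test(
    a: int,
    b: int,
    c: int,
    d: int,
    policy: str = "auto",
    ci_level: float = 0.95,
    ci_method: str = "woolf",
) -> ContingencyResult:
    """Test a 2x2 table for association.

    ``policy="auto"`` (default): Pearson chi-square with 1 df and no
    continuity correction when every expected cell count is >= 5 and no
    observed cell is zero, else Fisher's exact two-sided test.  ``policy``
    may force ``"chi_square"`` or ``"fisher_exact"``.
    """
    _check_margins(a, b, c, d)
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if policy == "auto":
        test = (
            "chi_square"
            if expected.min() >= 5 and min(a, b, c, d) > 0
            else "fisher_exact"
        )
    elif policy in ("chi_square", "fisher_exact"):
        test = policy
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if test == "chi_square":
        statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        statistic, p = stats.fisher_exact(table, alternative="two-sided")
    or_point, lo, hi = odds_ratio_ci(a, b, c, d, level=ci_level, method=ci_method)
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        statistic=float(statistic),
        p_value=float(p),
        test=test,
        odds_ratio=or_point,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        ci_method=ci_method,
    )


def lineage_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x 2 lineage-by-group count table.

    ``table`` is a mapping lineage -> (count_group1, count_group2) or an
    (r, 2) array.  Lineages with zero total are dropped with a warning.
    Returns (statistic, df, p) with df = r - 1.
    """
    import warnings

    if hasattr(table, "items"):
        arr = np.array([list(v) for _, v in sorted(table.items())], dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    keep = arr.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total lineage rows")
        arr = arr[keep]
    if arr.shape[0] < 2:
        raise DegenerateTableError("fewer than 2 surviving lineage categories")
    if (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError("a group column is all zero")
    statistic, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), int(df), float(p)


def t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float | None = None, sd2: float | None = None, n2: int | None = None,
    kind: str = "student",
    d_method: str = "rms_sd",
) -> SummaryComparison:
    """Two-sided t-test from summary statistics.

    ``kind="student"``: pooled-variance Student's t with df = n1 + n2 - 2.
    ``kind="paired"``: (mean1, sd1, n1) are the summaries of the paired
    differences; t = mean1 / (sd1/sqrt(n1)) with df = n1 - 1.
    """
    if kind == "paired":
        if sd1 <= 0:
            raise ValueError("sd of differences must be positive")
        if n1 < 2:
            raise ValueError("need n >= 2")
        df = n1 - 1
        t = mean1 / (sd1 / math.sqrt(n1))
        p = 2.0 * stats.t.sf(abs(t), df)
        d = abs(mean1) / sd1
        return SummaryComparison(
            mean1=mean1, sd1=sd1, n1=n1, mean2=0.0, sd2=0.0, n2=0,
            t=float(t), df=df, p_value=float(p), cohens_d=float(d),
            d_method="paired_sd", kind="paired",
        )
    if kind != "student":
        raise ValueError(f"unknown kind {kind!r}")
    if sd1 <= 0 or sd2 is None or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 is None or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    d = cohens_d_summary(mean1, sd1, mean2, sd2, method=d_method, n1=n1, n2=n2)
    return SummaryComparison(
        mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2,
        t=float(t), df=n1 + n2 - 2, p_value=float(p), cohens_d=d,
        d_method=d_method, kind="student",
    )


def cohens_d_summary(
    mean1: float, sd1: float, mean2: float, sd2: float,
    method: str = "rms_sd",
    n1: int | None = None, n2: int | None = None,
) -> float:
    """Cohen's d (reported non-negative) from group summaries.

    ``rms_sd`` (default): denominator sqrt((sd1^2 + sd2^2)/2) — Cohen's
    original equal-weight form.  ``pooled_df_weighted``: the df-weighted
    pooled SD sqrt(((n1-1)sd1^2 + (n2-1)sd2^2)/(n1+n2-2)), requiring n1, n2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if method == "rms_sd":
        denom = math.sqrt((sd1**2 + sd2**2) / 2.0)
    elif method == "pooled_df_weighted":
        if n1 is None or n2 is None or n1 < 2 or n2 < 2:
            raise ValueError("pooled_df_weighted requires n1, n2 >= 2")
        denom = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return abs(mean1 - mean2) / denom


def bonferroni(p_values, m: int | None = None):
    """Bonferroni-adjusted p-values (capped at 1); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    m = m if m is not None else p.size
    return np.minimum(p * m, 1.0)


def benjamini_hochberg(p_values):
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
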