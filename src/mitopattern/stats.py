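"""Statistical tests used across the pipeline.

The assay's region and condition comparisons use Welch's t-test and the
Mann-Whitney U test for pairwise contrasts, ordinary one-way ANOVA and
Kruskal-Wallis for multi-group contrasts, and ordinary least squares with
the zero-slope t-test for the regressions.  Results come back as small serializable records with
the statistic, degrees of freedom, p-value and per-group summaries.

Welch, ANOVA, Kruskal-Wallis and OLS are computed with scipy; the
Mann-Whitney U test is implemented here because the exact branch (full
enumeration over rank assignments with midrank ties, for combined n <= 12)
is part of this package's contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """Too few observations for the requested test."""


class DegenerateDataError(ValueError):
    """Data admit no informative test (zero variance where variance is needed)."""


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` may be fractional (Welch-Satterthwaite).  ``sided`` records
    whether ``pvalue`` is one- or two-sided.
    """

    test: str
    statistic: float
    df: float | None
    pvalue: float
    sided: str = "two-sided"
    groups: list[GroupSummary] = field(default_factory=list)
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LinearFit:
    """Ordinary least-squares line with the zero-slope t-test."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    pvalue: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


def _summaries(*samples) -> list[GroupSummary]:
    out = []
    for s in samples:
        s = np.asarray(s, dtype=float)
        out.append(
            GroupSummary(n=int(s.size), mean=float(np.mean(s)), sd=float(np.std(s, ddof=1)) if s.size > 1 else 0.0)
        )
    return out


# --------------------------------------------------------------------- Welch


def welch_t(x, y, sided: str = "two-sided") -> TestResult:
    """Welch's unequal-variance t-test.

    ``sided``: "two-sided", "greater" (mean(x) > mean(y)) or "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("Welch's t-test needs n >= 2 per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        # identical constants: no evidence against the null
        return TestResult("welch_t", 0.0, float(x.size + y.size - 2), 1.0, sided,
                          _summaries(x, y), note="zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False, alternative=sided)
    return TestResult(
        "welch_t",
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
        sided,
        _summaries(x, y),
    )


def welch_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    sided: str = "two-sided",
) -> TestResult:
    """Welch's t-test from per-group summary statistics.

    Used by the radial crossover search, where only per-bin means/SDs/counts
    are retained rather than raw pixel samples.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Welch's t-test needs n >= 2 per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    denom = math.sqrt(v1 + v2)
    if denom == 0:
        if mean1 == mean2:
            return TestResult("welch_t", 0.0, float(n1 + n2 - 2), 1.0, sided,
                              note="zero variance in both groups")
        raise DegenerateDataError("zero variance with unequal means")
    t = (mean1 - mean2) / denom
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if sided == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif sided == "greater":
        p = sps.t.sf(t, df)
    elif sided == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown sided={sided!r}")
    return TestResult("welch_t", float(t), float(df), float(min(p, 1.0)), sided)


# -------------------------------------------------------------- Mann-Whitney

#: combined-n cutoff below which the exact null distribution is enumerated
MW_EXACT_CUTOFF = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x against y with midrank ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y, sided: str = "two-sided",
                 exact_cutoff: int = MW_EXACT_CUTOFF) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    Exact p-value by full enumeration of all ``C(n1+n2, n1)`` group
    assignments of the pooled values when ``n1 + n2 <= exact_cutoff``;
    otherwise the tie-corrected normal approximation (with continuity
    correction).  Two-sided p doubles the smaller tail (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise InsufficientDataError("Mann-Whitney needs n >= 1 per group")
    u = _u_statistic(x, y)
    if n1 + n2 <= exact_cutoff:
        p = _mw_exact_p(x, y, u, sided)
        note = "exact enumeration"
    else:
        p = _mw_normal_p(x, y, u, sided)
        note = "normal approximation, tie-corrected"
    return TestResult("mann_whitney", u, None, float(p), sided, _summaries(x, y), note)


def _mw_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float, sided: str) -> float:
    """Permutation-exact p: enumerate every split of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = x.size
    n = pooled.size
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)]
    )
    total = us.size
    eps = 1e-9
    p_ge = np.count_nonzero(us >= u_obs - eps) / total
    p_le = np.count_nonzero(us <= u_obs + eps) / total
    if sided == "greater":
        return p_ge
    if sided == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _mw_normal_p(x: np.ndarray, y: np.ndarray, u_obs: float, sided: str) -> float:
    n1, n2 = x.size, y.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 1.0  # all values tied: no discrimination
    sigma = math.sqrt(sigma2)
    # continuity-corrected z for each tail
    z_ge = (u_obs - mu - 0.5) / sigma
    z_le = (u_obs - mu + 0.5) / sigma
    p_ge = sps.norm.sf(z_ge)
    p_le = sps.norm.cdf(z_le)
    if sided == "greater":
        return float(p_ge)
    if sided == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


# ------------------------------------------------------------------- k-group


def one_way_anova(groups) -> TestResult:
    """Ordinary one-way ANOVA (between/within F)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise InsufficientDataError("ANOVA needs n >= 2 per group")
    if all(np.var(a) == 0 for a in arrs) and len({float(a[0]) for a in arrs}) == 1:
        return TestResult("one_way_anova", 0.0,
                          float(len(arrs) - 1), 1.0, "two-sided",
                          _summaries(*arrs), note="all groups identical constants")
    f, p = sps.f_oneway(*arrs)
    df_between = len(arrs) - 1
    df_within = sum(a.size for a in arrs) - len(arrs)
    res = TestResult("one_way_anova", float(f), float(df_between), float(p),
                     "two-sided", _summaries(*arrs))
    res.note = f"df=({df_between}, {df_within})"
    return res


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs at least 2 groups")
    if any(a.size < 1 for a in arrs):
        raise InsufficientDataError("Kruskal-Wallis needs n >= 1 per group")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, float(len(arrs) - 1), 1.0,
                          "two-sided", _summaries(*arrs), note="all values tied")
    h, p = sps.kruskal(*arrs)
    return TestResult("kruskal_wallis", float(h), float(len(arrs) - 1), float(p),
                      "two-sided", _summaries(*arrs))


# ---------------------------------------------------------------------- OLS


def linear_regression(x, y) -> LinearFit:
    """OLS line fit with R² and the two-sided zero-slope t-test (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("linear regression needs n >= 3 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional; pairwise p-values are reported
    unadjusted by default, matching the assay's reporting convention)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
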