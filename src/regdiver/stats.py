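"""Shared statistical primitives.

Thin, contract-checked wrappers around scipy.stats / statsmodels used by the
regulon, conservation and dynamics modules. All tests in this package are
non-parametric (the underlying diversity and mutation-count distributions are
skewed and of unknown form): Wilcoxon signed-rank for paired comparisons,
Wilcoxon rank-sum for unpaired ones, Spearman rank correlation, one-sided
Fisher's exact test for 2x2 enrichment tables, and Holm-Bonferroni for
multiplicity. Exact null distributions are used at small sample sizes and
normal/t approximations beyond; the cutoffs are configurable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("less", "greater", "two-sided")

# Exact-path size cutoffs. Chosen so that enumeration stays instantaneous;
# beyond them the classical large-sample approximations are accurate.
EXACT_SIGNED_RANK_N = 25
EXACT_RANK_SUM_N = 12
EXACT_SPEARMAN_N = 8


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is the test's native statistic (W+, U, rho, odds ratio);
    for correlation results the statistic *is* rho.
    """

    statistic: float
    p_value: float
    alternative: str
    n: int
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _check_alternative(alternative: str) -> str:
    if alternative == "two_sided":
        alternative = "two-sided"
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    return alternative


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided",
                         exact_max_n: int = EXACT_SIGNED_RANK_N) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped (classical convention). The exact null
    distribution is used for n <= ``exact_max_n`` when the non-zero absolute
    differences are tie-free, otherwise a normal approximation with tie
    correction. If every pair is tied the test carries no evidence and
    p = 1 is returned with a warning.
    """
    alternative = _check_alternative(alternative)
    d = np.asarray(x, dtype=float)
    if y is not None:
        yarr = np.asarray(y, dtype=float)
        if yarr.shape != d.shape:
            raise ValueError("paired samples must have equal length")
        d = d - yarr
    if d.size == 0:
        raise ValueError("no pairs supplied")
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, alternative, 0, "wilcoxon-signed-rank")
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= exact_max_n and not ties) else "approx"
    res = sps.wilcoxon(nz, alternative=alternative, zero_method="wilcox",
                       method=method, correction=(method == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      int(nz.size), f"wilcoxon-signed-rank-{method}")


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_max_n: int = EXACT_RANK_SUM_N) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test on two independent samples."""
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      int(pooled.size), f"wilcoxon-rank-sum-{method}")


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("constant input vector: rho undefined")
    return float(rx @ ry) / denom


def spearman(x, y, alternative: str = "two-sided",
             exact_max_n: int = EXACT_SPEARMAN_N) -> TestResult:
    """Spearman rank correlation with midranks for ties.

    The p-value is computed by full permutation of one margin for
    n <= ``exact_max_n`` and by the t approximation otherwise.
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        rhos = np.array([_spearman_rho(x, np.asarray(perm))
                         for perm in itertools.permutations(y)])
        eps = 1e-12
        if alternative == "less":
            p = float(np.mean(rhos <= rho + eps))
        elif alternative == "greater":
            p = float(np.mean(rhos >= rho - eps))
        else:
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
        method = "spearman-permutation"
    else:
        res = sps.spearmanr(x, y, alternative=alternative)
        p = float(res.pvalue)
        method = "spearman-t"
    return TestResult(rho, min(p, 1.0), alternative, n, method)


def fisher_exact_one_sided(table, alternative: str = "greater") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    Returns the conditional (hypergeometric) tail probability; the statistic
    reported is the sample odds ratio (inf/nan on zero margins).
    """
    alternative = _check_alternative(alternative)
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(np.int64)
        if np.any(t_int != t) or np.any(t_int < 0):
            raise ValueError("table cells must be non-negative integers")
        t = t_int
    res = sps.fisher_exact(t, alternative=alternative)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(odds, float(res.pvalue), alternative, int(t.sum()),
                      "fisher-exact", extra={"table": t.tolist()})


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
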