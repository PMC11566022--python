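"""Shared statistical procedures with explicit, reproducible contracts.

Thin wrappers over scipy.stats / statsmodels so that every test used in
the pipeline has a single, documented entry point.  All p-values are
two-tailed.  Mann-Whitney uses exact enumeration for small samples
(both n <= 8, no ties) and the tie-corrected normal approximation with
continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _ss
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    method: str


def _as_array(x, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < min_n:
        raise ValueError(f"{name} must be 1-D with at least {min_n} values")
    return arr


def mann_whitney(x, y) -> TestResult:
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 8 and len(y) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), (len(x), len(y)),
                      f"mann-whitney ({method})")


def ks_2samp(x, y) -> TestResult:
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    res = _ss.ks_2samp(x, y, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), (len(x), len(y)),
                      "two-sample KS")


def kruskal_wallis(groups) -> TestResult:
    arrays = [_as_array(g, "group") for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    res = _ss.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue),
                      tuple(len(a) for a in arrays), "kruskal-wallis")


def welch_t(x, y) -> TestResult:
    x = _as_array(x, "x", min_n=2)
    y = _as_array(y, "y", min_n=2)
    res = _ss.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), (len(x), len(y)),
                      "welch t")


def one_sample_t(x, mu: float) -> TestResult:
    x = _as_array(x, "x", min_n=2)
    res = _ss.ttest_1samp(x, mu)
    return TestResult(float(res.statistic), float(res.pvalue), (len(x),),
                      "one-sample t")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_i = min_{j>=i} p_(j) * m / j."""
    p = _as_array(pvalues, "pvalues")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
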