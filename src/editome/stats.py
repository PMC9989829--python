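"""Exact-statistics helpers shared across the pipeline.

The sequencing-error model is a binomial B(k, n, p) with p the maximal
per-base error probability (0.001 for bases at Phred >= 30); the upper-tail
mass P(X >= k) is the p-value that k edited reads out of n arose from
sequencing error alone.  Multiple testing everywhere uses Benjamini-
Hochberg; enrichment tables use the two-sided Fisher exact test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


def binomial_upper_tail(k, n, p: float):
    """P(X >= k) for X ~ Binomial(n, p).  Vectorized over k and n."""
    k = np.asarray(k)
    n = np.asarray(n)
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    out = _sps.binom.sf(k - 1, n, p)
    return float(out) if out.ndim == 0 else out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for table [[a, b], [c, d]]."""
    return float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def binom_test_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial test of k successes in n at rate p."""
    if n == 0:
        return 1.0
    return float(_sps.binomtest(k, n, p, alternative="two-sided").pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, p)."""
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (t, p)."""
    t, p = _sps.ttest_rel(x, y)
    return float(t), float(p)
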