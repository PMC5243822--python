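"""Association and demographic statistics.

Connectivity-versus-MMSE Pearson correlation (with the usual t-based
two-sided p-value), the uncorrected 2x2 Pearson chi-square for sex
distributions, and the two-sample t-test (pooled or Welch) for continuous
demographics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

SIGNIFICANCE_LEVEL = 0.05


@dataclasses.dataclass
class AssociationRecord:
    feature: tuple[str, str] | str
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


def fc_mmse_correlation(fc_values, mmse, feature="fc") -> AssociationRecord:
    """Pearson correlation of one connectivity feature against MMSE across
    subjects; two-sided p from the t distribution with n-2 d.f."""
    x = np.asarray(fc_values, dtype=float).ravel()
    y = np.asarray(mmse, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("fc_values and mmse must align")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return AssociationRecord(feature, float(res.statistic), float(res.pvalue), x.size)


def chi_square_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 count table, 1 d.f."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.rint(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def two_sample_ttest(a, b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; returns (t, d.f., p).

    ``pooled`` assumes equal variances (n_a + n_b - 2 d.f.), ``welch`` uses
    the Satterthwaite approximation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both samples are constant: t undefined")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)
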