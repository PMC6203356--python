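"""Small shared statistics helpers: SEM and the two-sample Student t-test."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def sem(values) -> float:
    """Standard error of the mean (sample SD with n-1 denominator / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def student_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (equal-variance Student by default).

    Returns (t statistic, two-sided p). Raises on degenerate input: fewer
    than two observations per group, or zero pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires >= 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: degenerate t-test")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
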