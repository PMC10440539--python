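"""Study-level statistics: normality screening and paired comparisons.

The multilayer-vs-single-layer comparison is intrinsically paired (both
models are built from the same slice geometry), so the operative test is
the paired t test on per-patient differences, preceded by a one-sample
Kolmogorov-Smirnov check of the differences against a fitted normal.
Significance is declared at alpha = 0.05; no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PairedComparison", "ks_normality", "paired_t"]

ALPHA = 0.05


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired t test on (multi, single) per-patient scalars."""

    n: int
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    ks_statistic: float
    ks_p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def ks_normality(sample: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of the standardized sample against the
    standard normal, with the asymptotic KS p-value.

    Note this uses estimated mean/SD (the usual applied-normality screen);
    the asymptotic p is therefore conservative-free, not
    Lilliefors-corrected.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("KS normality check needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / sd
    d, _ = sps.kstest(z, "norm")
    p = float(sps.kstwobign.sf(np.sqrt(x.size) * d))
    return float(d), min(1.0, p)


def paired_t(multi: np.ndarray, single: np.ndarray) -> PairedComparison:
    """Two-sided paired t test; multi and single are per-patient scalars."""
    m = np.asarray(multi, dtype=float)
    s = np.asarray(single, dtype=float)
    if m.shape != s.shape or m.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if m.size < 2:
        raise ValueError("paired t test needs n >= 2")
    d = m - s
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences (degenerate pairing)")
    res = sps.ttest_rel(m, s)
    if d.size >= 5:
        ks_d, ks_p = ks_normality(d)
    else:
        ks_d, ks_p = np.nan, np.nan
    return PairedComparison(
        n=int(m.size), mean_difference=float(d.mean()),
        t_statistic=float(res.statistic), df=int(m.size - 1),
        p_value=float(res.pvalue), ks_statistic=ks_d, ks_p_value=ks_p,
    )
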