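"""Genome-wide significance thresholds for the scan p-values.

The headline rule is the proportion-based FDR threshold

    p_threshold = FDR * n / m

with ``n`` the number of SNPs reaching nominal p < 0.05 and ``m`` the total
number of (testable) SNPs; a SNP is called significant when its p-value
falls strictly below the threshold.  Classical Benjamini-Hochberg step-up
control is provided alongside as the standard comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["SignificanceCall", "fdr_threshold", "benjamini_hochberg"]


@dataclass
class SignificanceCall:
    threshold_p: float
    fdr: float
    n_below_05: int
    m_total: int
    significant_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "threshold_p": self.threshold_p,
            "fdr": self.fdr,
            "n_below_05": self.n_below_05,
            "m_total": self.m_total,
            "n_significant": int(len(self.significant_idx)),
        }


def fdr_threshold(p_values, fdr: float = 0.05) -> SignificanceCall:
    """Proportion-based FDR threshold ``fdr * n / m`` with strict calls.

    NaN p-values (untestable SNPs) are excluded from both ``n`` and ``m``
    and can never be significant.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr={fdr} must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    testable = ~np.isnan(p)
    if np.any((p[testable] < 0) | (p[testable] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(testable.sum())
    n = int((p[testable] < 0.05).sum())
    threshold = fdr * n / m if m > 0 else 0.0
    sig = np.flatnonzero(testable & (p < threshold))
    return SignificanceCall(
        threshold_p=threshold, fdr=fdr, n_below_05=n, m_total=m, significant_idx=sig
    )


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Indices significant under classical BH step-up control at level q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    testable = ~np.isnan(p)
    reject = np.zeros(p.size, dtype=bool)
    if testable.sum():
        reject[testable] = multipletests(p[testable], alpha=q, method="fdr_bh")[0]
    return np.flatnonzero(reject)
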