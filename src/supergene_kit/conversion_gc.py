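"""GC-bias test for gene conversion.

GC-biased gene conversion preferentially resolves A:C / G:T heteroduplex
mismatches toward G/C, so derived alleles introduced by conversion should be
GC-enriched relative to derived alleles shared through ancestry. The test
classifies polarized sites into their dominant pattern (ABBA / BABA / BBAA),
takes the GC indicator of the shared derived allele, and compares the
candidate-introgression set against the ancestry set with a one-sided Welch
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dstats import site_pattern_weights

__all__ = ["classify_sites_hard", "gc_indicator", "GcTestResult", "gc_bias_test"]


def classify_sites_hard(table: pd.DataFrame, trio: tuple[str, str, str]) -> np.ndarray:
    """Label each site by its strictly largest pattern weight.

    Returns an object array of labels in {"ABBA", "BABA", "BBAA", "none"};
    ties (including the all-zero case) are "none".
    """
    wa, wb, wc = site_pattern_weights(
        table[trio[0]].to_numpy(), table[trio[1]].to_numpy(), table[trio[2]].to_numpy()
    )
    w = np.stack([wa, wb, wc], axis=1)
    best = w.argmax(axis=1)
    strict = (w == w.max(axis=1, keepdims=True)).sum(axis=1) == 1
    labels = np.array(["ABBA", "BABA", "BBAA"], dtype=object)[best]
    labels[~strict] = "none"
    return labels


def gc_indicator(derived_base: str) -> int:
    """1 when the shared derived allele is G or C, 0 for A or T.

    Non-ACGT alleles raise; callers exclude (and log) such sites.
    """
    b = derived_base.upper()
    if b in "GC":
        return 1
    if b in "AT":
        return 0
    raise ValueError(f"non-ACGT derived allele {derived_base!r}")


@dataclass
class GcTestResult:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p_one_sided: float
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"GC mean A={self.mean_a:.3f} (n={self.n_a}) vs B={self.mean_b:.3f} "
            f"(n={self.n_b}); Welch t={self.t:.2f}, df={self.df:.0f}, "
            f"one-sided p={self.p_one_sided:.3g}"
        )


def gc_bias_test(set_a: np.ndarray, set_b: np.ndarray) -> GcTestResult:
    """Welch two-sample t-test of GC indicators, alternative mean(A) > mean(B)."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both site sets must be non-empty")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return GcTestResult(
                a.size, b.size, float(a.mean()), float(b.mean()),
                np.nan, np.nan, np.nan, degenerate=True,
            )
        t = np.inf if a.mean() > b.mean() else -np.inf
        return GcTestResult(
            a.size, b.size, float(a.mean()), float(b.mean()),
            t, float(a.size + b.size - 2), 0.0 if t > 0 else 1.0,
        )
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return GcTestResult(
        a.size, b.size, float(a.mean()), float(b.mean()),
        float(res.statistic), float(res.df), float(res.pvalue),
    )
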