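"""LD-based supergene delimitation and windowed diversity statistics.

The delimitation statistic follows the study design for inversion
polymorphisms: for each SNP, S is the sum of the distances (in bp) to all
other SNPs within 250 kb with which it is strongly linked (R^2 > 0.8).
Inside an inversion carried by a mixed panel of homokaryotypes, diagnostic
sites are in complete association, so S jumps by orders of magnitude at the
inversion boundaries; the boundary caller makes that visual signature
reproducible via two-means classification of the smoothed log profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "LinkedPairSet",
    "LdProfile",
    "dosage_r2",
    "ld_span_sum",
    "delimit_high_ld",
    "nucleotide_diversity_pi",
    "window_fst_dxy",
]


@dataclass
class LinkedPairSet:
    """Pairwise R^2 between SNPs closer than ``max_dist`` bp."""

    pos: np.ndarray  # positions of the profiled SNPs
    i: np.ndarray  # first site index per pair
    j: np.ndarray  # second site index per pair
    r2: np.ndarray
    max_dist: int
    n_omitted: int = 0  # pairs dropped for <2 informative samples / zero variance

    @property
    def distance(self) -> np.ndarray:
        return np.abs(self.pos[self.j] - self.pos[self.i])


@dataclass
class LdProfile:
    pos: np.ndarray
    s: np.ndarray  # per-SNP linkage-span sum, bp
    intervals: list[tuple[int, int]] = field(default_factory=list)


def dosage_r2(
    gm: GenotypeMatrix, max_dist: int = 250_000, chunk: int = 512
) -> LinkedPairSet:
    """Squared Pearson correlation of alt-allele dosages for nearby SNP pairs.

    Missing genotypes are excluded pairwise; pairs with fewer than two
    informative samples or zero variance at either site are omitted.
    Computed chunk-wise with mask-aware matrix products, so dense panels
    stay fast.
    """
    d = gm.dosage()
    pos = gm.pos
    m = (~np.isnan(d)).astype(np.float64)
    x = np.nan_to_num(d, nan=0.0)
    x2 = x * x
    n_sites = gm.n_sites
    out_i, out_j, out_r2 = [], [], []
    n_omitted = 0
    for a0 in range(0, n_sites, chunk):
        a1 = min(a0 + chunk, n_sites)
        b1 = np.searchsorted(pos, pos[a1 - 1] + max_dist, side="left")
        xa, ma, xa2 = x[a0:a1], m[a0:a1], x2[a0:a1]
        xb, mb, xb2 = x[a0:b1], m[a0:b1], x2[a0:b1]
        n = ma @ mb.T
        sx = xa @ mb.T
        sy = ma @ xb.T
        sxx = xa2 @ mb.T
        syy = ma @ xb2.T
        sxy = xa @ xb.T
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = n * sxx - sx * sx
            vy = n * syy - sy * sy
            r2 = (n * sxy - sx * sy) ** 2 / (vx * vy)
        ii, jj = np.meshgrid(
            np.arange(a0, a1), np.arange(a0, b1), indexing="ij"
        )
        within = (jj > ii) & (np.abs(pos[jj] - pos[ii]) < max_dist)
        valid = within & (n >= 2) & (vx > 0) & (vy > 0)
        n_omitted += int((within & ~valid).sum())
        out_i.append(ii[valid])
        out_j.append(jj[valid])
        out_r2.append(r2[valid])
    return LinkedPairSet(
        pos=pos.copy(),
        i=np.concatenate(out_i) if out_i else np.array([], dtype=int),
        j=np.concatenate(out_j) if out_j else np.array([], dtype=int),
        r2=np.clip(np.concatenate(out_r2), 0.0, 1.0) if out_r2 else np.array([]),
        max_dist=max_dist,
        n_omitted=n_omitted,
    )


def ld_span_sum(pairs: LinkedPairSet, r2_threshold: float = 0.8) -> LdProfile:
    """Per-SNP linkage-span S: summed distance to partners with R^2 strictly above threshold."""
    s = np.zeros(len(pairs.pos), dtype=np.float64)
    sel = pairs.r2 > r2_threshold
    dist = np.abs(pairs.pos[pairs.j[sel]] - pairs.pos[pairs.i[sel]]).astype(np.float64)
    np.add.at(s, pairs.i[sel], dist)
    np.add.at(s, pairs.j[sel], dist)
    return LdProfile(pos=pairs.pos.copy(), s=s)


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D two-means; returns a bool high-class label."""
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.zeros(x.shape, dtype=bool)
    c = np.array([lo, hi])
    for _ in range(max_iter):
        hi_cls = np.abs(x - c[1]) < np.abs(x - c[0])
        new = np.array(
            [x[~hi_cls].mean() if (~hi_cls).any() else c[0],
             x[hi_cls].mean() if hi_cls.any() else c[1]]
        )
        if np.allclose(new, c):
            break
        c = new
    return np.abs(x - c[1]) < np.abs(x - c[0])


def delimit_high_ld(
    profile: LdProfile, smooth_window: int = 25, gap_tolerance: int = 10
) -> list[tuple[int, int]]:
    """Call high-LD intervals from the linkage-span profile.

    S is smoothed by a centred rolling median over ``smooth_window`` SNPs,
    SNPs are split into high/low classes by two-means on log1p(smoothed S),
    and a high-LD interval is a maximal run of high-class SNPs tolerating up
    to ``gap_tolerance`` consecutive low-class SNPs inside. Intervals are
    half-open in bp: ``[first high SNP pos, last high SNP pos + 1)``.
    """
    if len(profile.s) < smooth_window:
        raise ValueError("fewer SNPs than the smoothing window")
    sm = (
        pd.Series(profile.s)
        .rolling(smooth_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    x = np.log1p(sm)
    if np.all(x == x[0]):
        profile.intervals = []
        return []
    high = _two_means_1d(x)
    intervals: list[tuple[int, int]] = []
    idx = np.flatnonzero(high)
    if idx.size == 0:
        profile.intervals = []
        return []
    run_start = idx[0]
    prev = idx[0]
    for k in idx[1:]:
        if k - prev - 1 > gap_tolerance:
            intervals.append((int(profile.pos[run_start]), int(profile.pos[prev]) + 1))
            run_start = k
        prev = k
    intervals.append((int(profile.pos[run_start]), int(profile.pos[prev]) + 1))
    profile.intervals = intervals
    return intervals


# ----------------------------------------------------------------------
def nucleotide_diversity_pi(
    gm: GenotypeMatrix, group: list[str], denominator_bp: float
) -> float:
    """Per-site nucleotide diversity within a group.

    pi = sum over sites of 2 p (1 - p) n / (n - 1), divided by the accessible
    length in bp supplied by the caller (so the denominator is
    masking-aware, not the count of variant sites).
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    idx = gm.sample_indices(group)
    g = gm.gt[:, idx, :]
    called = g != -1
    n = called.sum(axis=(1, 2)).astype(float)
    alt = ((g == 1) & called).sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
        h = np.where(n > 1, 2 * p * (1 - p) * n / (n - 1), 0.0)
    return float(h.sum() / denominator_bp)


def _group_freqs(gm: GenotypeMatrix, group: list[str]):
    idx = gm.sample_indices(group)
    g = gm.gt[:, idx, :]
    called = g != -1
    n = called.sum(axis=(1, 2)).astype(float)
    alt = ((g == 1) & called).sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return p, n


def window_fst_dxy(
    gm: GenotypeMatrix,
    groupA: list[str],
    groupB: list[str],
    window: int = 100_000,
    accessible_bp_per_window: float | None = None,
) -> pd.DataFrame:
    """Hudson's F_ST (ratio of sums) and d_XY in non-overlapping windows.

    F_ST = 1 - sum(pi_within) / sum(pi_between), aggregated over the sites
    of a window; d_XY sums pA(1-pB) + pB(1-pA) per site and divides by the
    accessible window length (the window size by default). Windows with no
    informative site are flagged missing.
    """
    if set(groupA) & set(groupB):
        raise ValueError("groups must be disjoint")
    pA, nA = _group_freqs(gm, groupA)
    pB, nB = _group_freqs(gm, groupB)
    ok = ~np.isnan(pA) & ~np.isnan(pB) & (nA > 1) & (nB > 1)
    hw = 0.5 * (
        2 * pA * (1 - pA) * nA / np.maximum(nA - 1, 1)
        + 2 * pB * (1 - pB) * nB / np.maximum(nB - 1, 1)
    )
    hb = pA * (1 - pB) + pB * (1 - pA)
    start = (gm.pos - 1) // window * window
    rows = []
    for w0 in range(0, int(gm.pos.max() // window + 1) * window, window):
        sel = (start == w0) & ok
        acc = accessible_bp_per_window or window
        if not sel.any():
            rows.append((w0, w0 + window, np.nan, np.nan, 0))
            continue
        sw, sb = hw[sel].sum(), hb[sel].sum()
        fst = 1 - sw / sb if sb > 0 else np.nan
        rows.append((w0, w0 + window, fst, sb / acc, int(sel.sum())))
    return pd.DataFrame(
        rows, columns=["start", "end", "fst", "dxy", "n_sites"]
    )
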