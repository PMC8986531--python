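"""Site-pattern introgression statistics: Patterson's D, f_dM and D_tree.

All frequency-based statistics work on outgroup-polarized derived-allele
frequencies. Weights follow the standard polarized-frequency formulation
with the outgroup fixed ancestral:

    w_ABBA = (1 - p1) p2 p3,  w_BABA = p1 (1 - p2) p3,  w_BBAA = p1 p2 (1 - p3)

D = sum(w_ABBA - w_BABA) / sum(w_ABBA + w_BABA), with significance from a
delete-one block jackknife over contiguous blocks of equal site count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "polarize_sites",
    "site_pattern_weights",
    "DStatResult",
    "patterson_d_jackknife",
    "orient_trio",
    "fdm_windows",
    "TreeTrioResult",
    "d_tree",
]


# ----------------------------------------------------------------------
def polarize_sites(
    gm: GenotypeMatrix, groups: dict[str, list[str]], outgroup: list[str]
) -> pd.DataFrame:
    """Polarize biallelic sites on the outgroup and compute derived frequencies.

    The ancestral allele is the allele carried by the outgroup; sites where
    the outgroup is missing, heterozygous or polymorphic are dropped, as are
    sites that are not biallelic. Returns a frame with one derived-frequency
    column per group plus the derived allele base and its GC indicator.
    """
    for s in outgroup:
        if s not in gm.samples:
            raise KeyError(f"outgroup sample {s!r} absent from the matrix")
    og_idx = gm.sample_indices(outgroup)
    og = gm.gt[:, og_idx, :].reshape(gm.n_sites, -1)
    og_called = og != MISSING
    has_call = og_called.any(axis=1)
    # outgroup monomorphic: all called alleles identical
    first = np.where(has_call, og[np.arange(gm.n_sites), og_called.argmax(axis=1)], -1)
    mono = has_call & np.all((og == first[:, None]) | ~og_called, axis=1)
    biallelic = np.array([len(a) == 1 for a in gm.alt])
    keep = mono & biallelic
    anc_allele = first  # 0 = ref ancestral, 1 = alt ancestral

    rows = {"chrom": gm.chrom[keep], "pos": gm.pos[keep]}
    der_is_alt = anc_allele[keep] == 0
    der_base = np.where(
        der_is_alt, [a[0] for a in (gm.alt[i] for i in np.flatnonzero(keep))], gm.ref[keep]
    )
    rows["derived_base"] = der_base
    rows["gc"] = np.array([b in "GC" for b in der_base], dtype=int)
    for name, members in groups.items():
        idx = gm.sample_indices(members)
        g = gm.gt[keep][:, idx, :]
        called = g != MISSING
        n = called.sum(axis=(1, 2)).astype(float)
        alt = ((g == 1) & called).sum(axis=(1, 2)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n > 0, alt / n, np.nan)
        rows[name] = np.where(der_is_alt, p_alt, 1 - p_alt)
    df = pd.DataFrame(rows)
    # need every group informative at the site
    return df.dropna(subset=list(groups)).reset_index(drop=True)


def site_pattern_weights(p1, p2, p3) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency weights of the ABBA, BABA and BBAA patterns."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    for p in (p1, p2, p3):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("derived frequencies must lie in [0, 1]")
    return (1 - p1) * p2 * p3, p1 * (1 - p2) * p3, p1 * p2 * (1 - p3)


# ----------------------------------------------------------------------
@dataclass
class DStatResult:
    trio: tuple[str, str, str]
    orientation: str  # "fix" | "BBAA"
    d: float
    se: float
    z: float
    p_value: float
    n_blocks: int
    sum_abba: float
    sum_baba: float
    sum_bbaa: float
    n_sites: int

    def summary(self) -> str:
        return (
            f"D({self.trio[0]},{self.trio[1]};{self.trio[2]}) [{self.orientation}] "
            f"= {self.d:.4f}  SE={self.se:.4f}  Z={self.z:.2f}  p={self.p_value:.3g}  "
            f"ABBA={self.sum_abba:.1f} BABA={self.sum_baba:.1f} BBAA={self.sum_bbaa:.1f}"
        )


def patterson_d_jackknife(
    table: pd.DataFrame,
    trio: tuple[str, str, str],
    blocks: int = 20,
    orientation: str = "fix",
) -> DStatResult:
    """Patterson's D with a delete-one block jackknife over contiguous blocks.

    Sites must be in genome order; they are split into ``blocks`` contiguous
    blocks of (nearly) equal site count. Z = D / SE with the standard
    delete-one jackknife standard error.
    """
    if len(table) < blocks:
        raise ValueError("fewer sites than jackknife blocks")
    wa, wb, wc = site_pattern_weights(
        table[trio[0]].to_numpy(), table[trio[1]].to_numpy(), table[trio[2]].to_numpy()
    )
    num, den = wa - wb, wa + wb
    tot_num, tot_den = num.sum(), den.sum()
    if tot_den == 0:
        return DStatResult(
            trio, orientation, np.nan, np.nan, np.nan, np.nan, blocks,
            float(wa.sum()), float(wb.sum()), float(wc.sum()), len(table),
        )
    d = tot_num / tot_den
    edges = np.linspace(0, len(table), blocks + 1).astype(int)
    d_del = np.empty(blocks)
    for k in range(blocks):
        sl = slice(edges[k], edges[k + 1])
        dk = tot_den - den[sl].sum()
        d_del[k] = (tot_num - num[sl].sum()) / dk if dk != 0 else d
    m = blocks
    se = float(np.sqrt((m - 1) / m * ((d_del - d_del.mean()) ** 2).sum()))
    z = d / se if se > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else np.nan
    return DStatResult(
        trio, orientation, float(d), se, float(z), float(p), blocks,
        float(wa.sum()), float(wb.sum()), float(wc.sum()), len(table),
    )


def orient_trio(
    table: pd.DataFrame,
    trio: tuple[str, str, str],
    mode: str = "BBAA",
    fixed_topology: tuple[str, str] | None = None,
) -> tuple[str, str, str]:
    """Assign P1/P2/P3 roles to a trio.

    mode="BBAA": permute roles so that the BBAA pattern sum is the largest,
    then order P1/P2 so that sum(ABBA) >= sum(BABA), which makes D_BBAA
    non-negative. Ties between pattern sums resolve deterministically by
    label order. mode="fix": P1, P2 are the sister pair named by
    ``fixed_topology`` (in that order); the sign of D is left free.
    """
    if mode == "fix":
        if fixed_topology is None:
            raise ValueError("mode='fix' requires fixed_topology naming the sister pair")
        p1, p2 = fixed_topology
        (p3,) = [t for t in trio if t not in fixed_topology]
        return (p1, p2, p3)
    if mode != "BBAA":
        raise ValueError("mode must be 'fix' or 'BBAA'")
    best = None
    for perm in sorted(permutations(sorted(trio))):
        wa, wb, wc = site_pattern_weights(
            table[perm[0]].to_numpy(), table[perm[1]].to_numpy(), table[perm[2]].to_numpy()
        )
        key = (round(float(wc.sum()), 12), round(float(wa.sum() - wb.sum()), 12))
        if best is None or key > best[0]:
            best = (key, perm)
    return best[1]


# ----------------------------------------------------------------------
def fdm_windows(
    table: pd.DataFrame,
    trio: tuple[str, str, str],
    window_snps: int = 50,
    step_snps: int = 25,
) -> pd.DataFrame:
    """Windowed f_dM introgression proportion over sliding SNP windows.

    Per site the numerator is w_ABBA - w_BABA. The denominator substitutes
    the donor population P_D = argmax(p2, p3) for both P2 and P3 when
    p2 >= p1 (positive direction), or P_D = argmax(p1, p3) for both P1 and
    P3 with negated sign when p2 < p1. Window sums of numerator over
    denominator give f_dM in [-1, 1]; windows with zero denominator are
    flagged missing.
    """
    p1 = table[trio[0]].to_numpy()
    p2 = table[trio[1]].to_numpy()
    p3 = table[trio[2]].to_numpy()
    wa, wb, _ = site_pattern_weights(p1, p2, p3)
    num = wa - wb
    den = np.empty_like(num)
    fwd = p2 >= p1
    pd23 = np.maximum(p2, p3)
    den[fwd] = ((1 - p1) * pd23 * pd23 - p1 * (1 - pd23) * pd23)[fwd]
    pd13 = np.maximum(p1, p3)
    den[~fwd] = -((1 - pd13) * p2 * pd13 - pd13 * (1 - p2) * pd13)[~fwd]
    rows = []
    n = len(table)
    start = 0
    w = 0
    while start < n:
        end = min(start + window_snps, n)
        s_num, s_den = num[start:end].sum(), den[start:end].sum()
        fdm = s_num / s_den if s_den != 0 else np.nan
        rows.append((w, start, end, end - start, fdm))
        if end == n:
            break
        start += step_snps
        w += 1
    return pd.DataFrame(rows, columns=["window", "first_snp", "last_snp", "n_snps", "fdm"])


# ----------------------------------------------------------------------
@dataclass
class TreeTrioResult:
    trio: tuple[str, str, str]
    counts: dict  # sister-pair -> count
    f_1st: int
    f_2nd: int
    f_3rd: int
    d_tree: float  # nan when f_2nd + f_3rd == 0


def _manual_mrca(a, b):
    anc = []
    nd = a
    while nd is not None:
        anc.append(nd)
        nd = nd.parent_node
    anc_ids = {id(x) for x in anc}
    nd = b
    while nd is not None:
        if id(nd) in anc_ids:
            return nd
        nd = nd.parent_node
    raise RuntimeError("disconnected leaves")  # pragma: no cover


def d_tree(trees, trio: tuple[str, str, str], outgroup: str | None = None) -> TreeTrioResult:
    """Tree-based D: D_tree = (f_2nd - f_3rd) / (f_2nd + f_3rd).

    For each rooted tree the sister pair of the trio is the pair whose MRCA
    does not contain the third taxon; polytomies that leave no resolved pair
    contribute to no count. Ties between pair frequencies are broken by
    lexicographic pair label, so results are deterministic.
    """
    import dendropy

    pairs = [tuple(sorted(p)) for p in ((trio[0], trio[1]), (trio[0], trio[2]), (trio[1], trio[2]))]
    counts = {p: 0 for p in pairs}
    for t in trees:
        if isinstance(t, str):
            t = dendropy.Tree.get(data=t, schema="newick")
        if outgroup is not None:
            og = t.find_node_with_taxon_label(outgroup)
            if og is not None:
                t.to_outgroup_position(og, update_bipartitions=True)
        leaf = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
        if not set(trio) <= set(leaf):
            raise ValueError("tree lacks one of the trio taxa")
        for a, b in pairs:
            c = [x for x in trio if x not in (a, b)][0]
            mrca = _manual_mrca(leaf[a], leaf[b])
            desc = {lf.taxon.label for lf in mrca.leaf_iter()}
            if c not in desc:
                counts[(a, b)] += 1
                break
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))  # tie: label order
    f1, f2, f3 = (ordered[k][1] for k in range(3))
    dt = (f2 - f3) / (f2 + f3) if (f2 + f3) > 0 else np.nan
    return TreeTrioResult(trio, counts, f1, f2, f3, float(dt))
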