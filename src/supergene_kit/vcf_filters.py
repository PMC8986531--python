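"""Genotype masks and site filters for population-level variant calls.

The canonical pipeline order is: genotype masking (GQ/DP), the
length-dependent indel-proximity filter, site-level filters (missingness,
minor allele count), then restriction to biallelic variable sites. Each
filter is idempotent and only changes membership -- retained genotype values
are never altered (masking excepted, which is exactly its job).
"""

from __future__ import annotations

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "mask_genotypes",
    "indel_proximity_filter",
    "site_filters",
    "restrict_biallelic",
    "apply_standard_pipeline",
]


def mask_genotypes(
    gm: GenotypeMatrix,
    min_gq: int = 20,
    min_dp: int = 3,
    max_dp: int = 80,
) -> GenotypeMatrix:
    """Set genotypes to missing when GQ < min_gq, DP < min_dp or DP > max_dp.

    All inequalities are strict, so a genotype at exactly GQ=20 or DP=3 or
    DP=80 is retained. Raises if the matrix carries no DP or GQ fields.
    """
    if gm.dp is None:
        raise ValueError("genotype matrix has no DP field; cannot mask on depth")
    if gm.gq is None:
        raise ValueError("genotype matrix has no GQ field; cannot mask on quality")
    out = gm.copy()
    bad = (out.gq < min_gq) | (out.dp < min_dp) | (out.dp > max_dp)
    out.gt[bad] = MISSING
    out.filter_log.append(
        {
            "filter": "mask_genotypes",
            "min_gq": min_gq,
            "min_dp": min_dp,
            "max_dp": max_dp,
            "n_masked": int(bad.sum()),
        }
    )
    return out


def _proximity_window(indel_len: np.ndarray) -> np.ndarray:
    """Exclusion window in bp around an indel, by indel length.

    10 bp for indels of 5 bp or longer; 5 bp for 3-4 bp; 3 bp for 2 bp;
    2 bp for 1 bp indels.
    """
    w = np.full(indel_len.shape, 10, dtype=np.int64)
    w[indel_len <= 4] = 5
    w[indel_len == 2] = 3
    w[indel_len == 1] = 2
    return w


def indel_proximity_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop SNPs close to indels, then drop the indels themselves.

    A SNP is removed when its distance to any indel's reference footprint
    ``[pos, pos + len(ref) - 1]`` is within the length-dependent window
    (see :func:`_proximity_window`). Distance is the minimum gap in bp, so a
    SNP inside the footprint has distance zero.
    """
    indel_len = gm.indel_length()
    is_indel = indel_len > 0
    if not is_indel.any():
        out = gm.copy()
        out.filter_log.append(
            {"filter": "indel_proximity", "n_snps_dropped": 0, "n_indels_dropped": 0}
        )
        return out
    keep = ~is_indel
    windows = _proximity_window(indel_len[is_indel])
    ind_chrom = gm.chrom[is_indel]
    ind_start = gm.pos[is_indel]
    ind_end = ind_start + np.array(
        [len(gm.ref[i]) - 1 for i in np.flatnonzero(is_indel)], dtype=np.int64
    )
    snp_idx = np.flatnonzero(~is_indel)
    n_snps_dropped = 0
    for c in dict.fromkeys(gm.chrom):
        sel = ind_chrom == c
        if not sel.any():
            continue
        lo = ind_start[sel] - windows[sel]
        hi = ind_end[sel] + windows[sel]
        s_on_c = snp_idx[gm.chrom[snp_idx] == c]
        p = gm.pos[s_on_c]
        # a SNP is hit if it lies inside any [lo, hi] interval
        hit = np.zeros(p.shape, dtype=bool)
        order = np.argsort(lo)
        lo_s, hi_s = lo[order], hi[order]
        j = np.searchsorted(lo_s, p, side="right")
        # check candidate intervals whose lo <= pos; running max of hi suffices
        run_hi = np.maximum.accumulate(hi_s)
        hit = (j > 0) & (p <= run_hi[np.maximum(j - 1, 0)])
        drop = s_on_c[hit]
        keep[drop] = False
        n_snps_dropped += int(hit.sum())
    out = gm.take_sites(np.flatnonzero(keep))
    out.filter_log.append(
        {
            "filter": "indel_proximity",
            "n_snps_dropped": n_snps_dropped,
            "n_indels_dropped": int(is_indel.sum()),
        }
    )
    return out


def site_filters(
    gm: GenotypeMatrix, max_missing: float = 0.8, min_mac: int = 20
) -> GenotypeMatrix:
    """Drop sites with missing fraction > max_missing or minor allele count < min_mac.

    Both cutoffs are strict, so a site at exactly 80% missing or MAC 20 is
    retained. The minor allele count is computed over called alleles; for a
    monomorphic site it is zero, so min_mac >= 1 removes invariant sites.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    miss = gm.missing_mask().mean(axis=1)
    n_sites = gm.n_sites
    mac = np.zeros(n_sites, dtype=np.int64)
    for i in range(n_sites):
        alleles = gm.gt[i][gm.gt[i] != MISSING]
        if alleles.size == 0:
            mac[i] = 0
            continue
        counts = np.bincount(alleles)
        counts = counts[counts > 0]
        mac[i] = 0 if counts.size < 2 else int(np.sort(counts)[-2])
    keep = (miss <= max_missing) & (mac >= min_mac)
    out = gm.take_sites(keep)
    out.filter_log.append(
        {
            "filter": "site_filters",
            "max_missing": max_missing,
            "min_mac": min_mac,
            "n_dropped": int((~keep).sum()),
        }
    )
    return out


def restrict_biallelic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites with exactly two observed alleles among called genotypes."""
    keep = np.zeros(gm.n_sites, dtype=bool)
    for i in range(gm.n_sites):
        alleles = gm.gt[i][gm.gt[i] != MISSING]
        keep[i] = np.unique(alleles).size == 2
    out = gm.take_sites(keep)
    out.filter_log.append(
        {"filter": "restrict_biallelic", "n_dropped": int((~keep).sum())}
    )
    return out


def apply_standard_pipeline(
    gm: GenotypeMatrix,
    min_gq: int = 20,
    min_dp: int = 3,
    max_dp: int = 80,
    max_missing: float = 0.8,
    min_mac: int = 20,
) -> GenotypeMatrix:
    """Canonical order: mask -> indel proximity -> site filters -> biallelic."""
    gm = mask_genotypes(gm, min_gq=min_gq, min_dp=min_dp, max_dp=max_dp)
    gm = indel_proximity_filter(gm)
    gm = site_filters(gm, max_missing=max_missing, min_mac=min_mac)
    return restrict_biallelic(gm)
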