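"""Ancestry painting and heterozygous-tract detection.

Paints individual genotypes at haplotype-informative sites (near-fixed
frequency contrast between two haplotype groups) and scans for long runs at
which designated focal individuals are jointly heterozygous -- the signature
of a double-crossover tract exchanged between inversion arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "informative_sites",
    "PaintingMatrix",
    "paint_genotypes",
    "TractCall",
    "detect_het_tract",
]

HOM_A, HOM_B, HET, MISS = 0, 1, 2, 3
_STATE_NAMES = np.array(["homA", "homB", "het", "missing"], dtype=object)


def informative_sites(
    gm: GenotypeMatrix,
    groupA: list[str],
    groupB: list[str],
    max_missing: float = 0.1,
    f_high: float = 0.9,
    f_low: float = 0.1,
) -> pd.DataFrame:
    """Haplotype-informative sites between two groups.

    A site is kept when its missing-genotype fraction over the two groups is
    strictly below ``max_missing`` and one allele reaches frequency
    >= ``f_high`` in one group while staying <= ``f_low`` in the other
    (frequencies over called alleles only). The returned frame records which
    allele index tags group A and which tags group B.
    """
    if not groupA or not groupB:
        raise ValueError("both groups must be non-empty")
    ia = gm.sample_indices(groupA)
    ib = gm.sample_indices(groupB)
    both = np.concatenate([ia, ib])
    miss_frac = (gm.gt[:, both, :] == MISSING).any(axis=2).mean(axis=1)

    def freq(idx):
        g = gm.gt[:, idx, :]
        called = g != MISSING
        n = called.sum(axis=(1, 2)).astype(float)
        alt = ((g == 1) & called).sum(axis=(1, 2)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / n, np.nan)

    fa, fb = freq(ia), freq(ib)
    alt_tags_a = (fa >= f_high) & (fb <= f_low)
    alt_tags_b = (fb >= f_high) & (fa <= f_low)
    keep = (miss_frac < max_missing) & (alt_tags_a | alt_tags_b)
    return pd.DataFrame(
        {
            "site_index": np.flatnonzero(keep),
            "pos": gm.pos[keep],
            "allele_a": np.where(alt_tags_a[keep], 1, 0),
            "allele_b": np.where(alt_tags_a[keep], 0, 1),
        }
    )


@dataclass
class PaintingMatrix:
    individuals: list[str]
    pos: np.ndarray
    states: np.ndarray  # (n_sites, n_individuals) codes HOM_A/HOM_B/HET/MISS
    sites: pd.DataFrame = field(repr=False, default=None)

    def state_names(self) -> np.ndarray:
        return _STATE_NAMES[self.states]


def paint_genotypes(
    gm: GenotypeMatrix, sites: pd.DataFrame, individuals: list[str]
) -> PaintingMatrix:
    """Paint each individual at the informative sites.

    States: homA (two group-A alleles), homB, het (one of each), missing
    (any missing allele).
    """
    idx = gm.sample_indices(individuals)
    si = sites["site_index"].to_numpy()
    g = gm.gt[np.ix_(si, idx)]
    a = sites["allele_a"].to_numpy()[:, None]
    b = sites["allele_b"].to_numpy()[:, None]
    n_a = ((g == a[..., None]).sum(axis=2)).astype(np.int8)
    n_b = ((g == b[..., None]).sum(axis=2)).astype(np.int8)
    any_miss = (g == MISSING).any(axis=2)
    states = np.full(n_a.shape, MISS, dtype=np.int8)
    states[(n_a == 2)] = HOM_A
    states[(n_b == 2)] = HOM_B
    states[(n_a == 1) & (n_b == 1)] = HET
    states[any_miss] = MISS
    return PaintingMatrix(
        individuals=list(individuals), pos=sites["pos"].to_numpy(), states=states,
        sites=sites,
    )


@dataclass
class TractCall:
    individuals: tuple[str, ...]
    start: int  # position of the first informative site in the run
    end: int  # position of the last informative site in the run
    n_sites: int
    first_site: int  # index into the painting matrix
    last_site: int


def detect_het_tract(
    pm: PaintingMatrix,
    focal: list[str],
    min_run: int = 5,
    max_miss_in_run: int = 0,
) -> list[TractCall]:
    """Find maximal runs where every focal individual is heterozygous.

    Within a run, up to ``max_miss_in_run`` missing states are tolerated per
    individual (hom states always terminate the run); run endpoints are
    trimmed to jointly heterozygous sites. Runs shorter than ``min_run``
    sites are discarded.
    """
    cols = [pm.individuals.index(f) for f in focal]
    s = pm.states[:, cols]
    all_het = (s == HET).all(axis=1)
    het_or_miss = ((s == HET) | (s == MISS)).all(axis=1)
    n_sites = s.shape[0]
    calls: list[TractCall] = []
    i = 0
    while i < n_sites:
        if not all_het[i]:
            i += 1
            continue
        miss_count = np.zeros(len(cols), dtype=int)
        j = i
        last_ok = i
        while j < n_sites and het_or_miss[j]:
            miss_here = pm.states[j, cols] == MISS
            if miss_here.any():
                miss_count += miss_here
                if (miss_count > max_miss_in_run).any():
                    break
            else:
                last_ok = j
            j += 1
        n_run = last_ok - i + 1
        if n_run >= min_run:
            calls.append(
                TractCall(
                    individuals=tuple(focal),
                    start=int(pm.pos[i]),
                    end=int(pm.pos[last_ok]),
                    n_sites=int(all_het[i : last_ok + 1].sum()),
                    first_site=i,
                    last_site=last_ok,
                )
            )
        i = max(j, last_ok + 1)
    return calls
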