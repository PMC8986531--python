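"""Core genotype container and plain-text I/O.

The :class:`GenotypeMatrix` is the substrate of every population statistic in
this package: a sites x samples table of diploid genotype calls with per-call
read depth (DP) and Phred-scaled genotype quality (GQ). Sites are kept in
genome order (strictly increasing position within a chromosome). Missing
alleles are coded ``-1``.

VCF input goes through :mod:`cyvcf2`; output is written as uncompressed
VCFv4.2 text with ``GT:DP:GQ`` fields so that round-trips are lossless for
the fields this package uses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x sites genotype matrix with DP/GQ fields.

    Attributes
    ----------
    samples : list of str
        Sample names, column order of all per-sample arrays.
    chrom : ndarray of str, shape (n_sites,)
    pos : ndarray of int, shape (n_sites,)
        1-based positions, strictly increasing within each chromosome.
    ref : ndarray of str, shape (n_sites,)
    alt : list of tuple of str
        Alternate alleles per site (usually one).
    gt : ndarray of int8, shape (n_sites, n_samples, 2)
        Allele indices (0=ref, 1=first alt, ...), -1 for missing.
    dp, gq : ndarray of int32, shape (n_sites, n_samples)
        Read depth and genotype quality; -1 where the field is absent.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list[tuple[str, ...]]
    gt: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    filter_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{(self.n_sites, self.n_samples, 2)}"
            )
        for name in ("dp", "gq"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=np.int32))
        # positions strictly increasing within chromosome
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        idx = []
        for n in names:
            try:
                idx.append(self.samples.index(n))
            except ValueError:
                raise KeyError(f"sample {n!r} not in matrix") from None
        return np.asarray(idx, dtype=np.intp)

    def indel_length(self) -> np.ndarray:
        """Length of each indel site: max(len(ref), len(longest alt)) - 1.

        Zero for SNPs (all alleles length 1).
        """
        out = np.zeros(self.n_sites, dtype=np.int64)
        for i, (r, alts) in enumerate(zip(self.ref, self.alt)):
            longest = max([len(r)] + [len(a) for a in alts]) if alts else len(r)
            out[i] = longest - 1
        return out

    def is_indel(self) -> np.ndarray:
        return self.indel_length() > 0

    def dosage(self, alt_index: int = 1) -> np.ndarray:
        """Alt-allele dosage per genotype: 0/1/2, NaN where any allele missing."""
        d = (self.gt == alt_index).sum(axis=2).astype(float)
        d[(self.gt == MISSING).any(axis=2)] = np.nan
        return d

    def missing_mask(self) -> np.ndarray:
        """(sites, samples) bool: genotype has any missing allele."""
        return (self.gt == MISSING).any(axis=2)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            gt=self.gt[index],
            dp=None if self.dp is None else self.dp[index],
            gq=None if self.gq is None else self.gq[index],
            filter_log=list(self.filter_log),
        )

    def take_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=[tuple(a) for a in self.alt],
            gt=self.gt[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            filter_log=list(self.filter_log),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=[tuple(a) for a in self.alt],
            gt=self.gt.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            filter_log=[dict(d) for d in self.filter_log],
        )

    # ------------------------------------------------------------------
    def to_vcf(self, path: str | os.PathLike) -> None:
        """Write an uncompressed VCFv4.2 file with GT:DP:GQ."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            for c in dict.fromkeys(self.chrom):
                ln = int(self.pos[self.chrom == c].max()) + 1000
                fh.write(f"##contig=<ID={c},length={ln}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            has_dp = self.dp is not None
            has_gq = self.gq is not None
            for i in range(self.n_sites):
                alt = ",".join(self.alt[i]) if self.alt[i] else "."
                cells = []
                for j in range(self.n_samples):
                    a, b = self.gt[i, j]
                    gtstr = ("." if a == MISSING else str(a)) + "/" + (
                        "." if b == MISSING else str(b)
                    )
                    dp = str(self.dp[i, j]) if has_dp else "."
                    gq = str(self.gq[i, j]) if has_gq else "."
                    cells.append(f"{gtstr}:{dp}:{gq}")
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\t{self.ref[i]}\t{alt}"
                    f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str | os.PathLike) -> "GenotypeMatrix":
        """Read a VCF (plain or bgzipped) via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        chrom, pos, ref, alt, gts, dps, gqs = [], [], [], [], [], [], []
        any_dp = any_gq = False
        for v in vcf:
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(tuple(v.ALT))
            g = np.array([row[:2] for row in v.genotypes], dtype=np.int8)
            gts.append(g)
            dp = v.format("DP")
            gq = v.format("GQ")
            if dp is not None:
                any_dp = True
                dps.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
            else:
                dps.append(np.full(len(samples), -1, dtype=np.int32))
            if gq is not None:
                any_gq = True
                gqs.append(np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32))
            else:
                gqs.append(np.full(len(samples), -1, dtype=np.int32))
        vcf.close()
        n = len(pos)
        return cls(
            samples=samples,
            chrom=np.array(chrom, dtype=object),
            pos=np.array(pos, dtype=np.int64),
            ref=np.array(ref, dtype=object),
            alt=alt,
            gt=np.array(gts, dtype=np.int8).reshape(n, len(samples), 2),
            dp=np.array(dps, dtype=np.int32) if any_dp else None,
            gq=np.array(gqs, dtype=np.int32) if any_gq else None,
        )


# ----------------------------------------------------------------------
def read_groups(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a two-column sample-to-group TSV into an ordered mapping."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, grp = line.split("\t")[:2]
            groups.setdefault(grp, []).append(sample)
    return groups


def write_groups(groups: Mapping[str, Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for grp, members in groups.items():
            for s in members:
                fh.write(f"{s}\t{grp}\n")
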