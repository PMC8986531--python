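"""Assembly-comparison utilities.

Four pieces: a strict three-way consensus mask over alternative alignments
of the same genome pair (only columns on which all three alignment methods
agree are kept), windowed uncorrected p-distances relative to an outgroup,
Fitch small-parsimony scoring for hemiplasy filtering of window alignments,
and classification of split contig alignments at candidate inversion
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusAlignment",
    "strict_consensus_mask",
    "window_p_distance",
    "ParsimonyResult",
    "fitch_score",
    "AlignmentBlock",
    "BreakpointCall",
    "classify_contig_breakpoints",
]

MISSING_BASE = "."


# ----------------------------------------------------------------------
@dataclass
class ConsensusAlignment:
    """Reference-coordinate consensus: per-genome base or missing per column."""

    reference: np.ndarray  # (L,) single characters
    genomes: dict = field(default_factory=dict)  # name -> (L,) chars, '.' = masked

    @property
    def length(self) -> int:
        return len(self.reference)

    def add(self, name: str, other: "ConsensusAlignment") -> None:
        if not np.array_equal(self.reference, other.reference):
            raise ValueError("consensus alignments disagree on the reference sequence")
        self.genomes.update({name: other.genomes[k] for k in other.genomes})


def _degap(ref_row: str, qry_row: str) -> tuple[np.ndarray, np.ndarray]:
    """Drop columns that gap the reference; keep reference coordinates."""
    r = np.array(list(ref_row.upper()), dtype="U1")
    q = np.array(list(qry_row.upper()), dtype="U1")
    if r.shape != q.shape:
        raise ValueError("alignment rows differ in length")
    keep = r != "-"
    return r[keep], q[keep]


def strict_consensus_mask(
    alnA: tuple[str, str],
    alnB: tuple[str, str],
    alnC: tuple[str, str],
    genome: str = "query",
) -> ConsensusAlignment:
    """Strict consensus of three alignments of the same genome pair.

    Each alignment is a (reference_row, query_row) pair of equal-length gapped
    strings. Columns gapping the reference are deleted (the output preserves
    reference coordinates); a column keeps its query base only when all three
    alignments present the identical base there, otherwise it is missing.
    The three degapped reference rows must agree, else an error is raised.
    """
    refs, qrys = [], []
    for aln in (alnA, alnB, alnC):
        r, q = _degap(*aln)
        refs.append(r)
        qrys.append(q)
    if not (np.array_equal(refs[0], refs[1]) and np.array_equal(refs[0], refs[2])):
        raise ValueError("the three alignments disagree on the reference sequence")
    agree = (qrys[0] == qrys[1]) & (qrys[0] == qrys[2]) & (qrys[0] != "-")
    out = np.where(agree, qrys[0], MISSING_BASE)
    return ConsensusAlignment(reference=refs[0], genomes={genome: out})


def window_p_distance(
    cons: ConsensusAlignment,
    focal: str,
    outgroup: str,
    window: int = 100_000,
    min_informative: int = 10_000,
) -> pd.DataFrame:
    """Uncorrected p-distances (and their ratio) in non-overlapping windows.

    Per window: d = mismatching columns / columns informative in both the
    reference and the genome; the ratio d_focal / d_out is the
    outgroup-relative divergence. Windows with fewer than ``min_informative``
    informative columns in either comparison are flagged missing.
    """
    ref = cons.reference
    rows = []
    for name in (focal, outgroup):
        if name not in cons.genomes:
            raise KeyError(f"genome {name!r} not in consensus")
    f = cons.genomes[focal]
    o = cons.genomes[outgroup]
    L = cons.length
    for w0 in range(0, L, window):
        sl = slice(w0, min(w0 + window, L))
        r = ref[sl]
        inf_f = (f[sl] != MISSING_BASE) & (r != MISSING_BASE)
        inf_o = (o[sl] != MISSING_BASE) & (r != MISSING_BASE)
        n_f, n_o = int(inf_f.sum()), int(inf_o.sum())
        if n_f < min_informative or n_o < min_informative:
            rows.append((w0, sl.stop, np.nan, np.nan, np.nan, min(n_f, n_o)))
            continue
        d_f = float((f[sl][inf_f] != r[inf_f]).mean())
        d_o = float((o[sl][inf_o] != r[inf_o]).mean())
        ratio = d_f / d_o if d_o > 0 else np.nan
        rows.append((w0, sl.stop, d_f, d_o, ratio, min(n_f, n_o)))
    return pd.DataFrame(
        rows, columns=["start", "end", "d_focal", "d_out", "ratio", "n_informative"]
    )


# ----------------------------------------------------------------------
@dataclass
class ParsimonyResult:
    n_var: int  # variable columns
    allele_excess: int  # sum over variable columns of (k_i - 1)
    score: int  # Fitch parsimony score P
    hemiplasy_excess: int  # H = P - sum(k_i - 1)

    def passes(self, threshold: int = 10) -> bool:
        return self.hemiplasy_excess <= threshold


_FULL = frozenset("ACGT")


def fitch_score(
    sequences: Mapping[str, str], tree, excess_mode: str = "lower_bound"
) -> ParsimonyResult:
    """Fitch small-parsimony score of an alignment on a tree, plus hemiplasy excess.

    Missing and gap characters contribute the full state set. The hemiplasy
    excess is H = P - sum(k_i - 1) with k_i the number of distinct observed
    states per variable column (the parsimony lower bound); with
    ``excess_mode="n_var"`` the alternative H = P - n_var is used instead
    (identical for strictly biallelic columns).
    """
    import dendropy

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for t in tips:
        if t not in sequences:
            raise KeyError(f"tree tip {t!r} has no sequence")
    length = len(next(iter(sequences.values())))
    if any(len(sequences[t]) != length for t in tips):
        raise ValueError("sequences differ in length")

    n_var = 0
    allele_excess = 0
    score = 0
    for col in range(length):
        chars = {t: sequences[t][col].upper() for t in tips}
        observed = {c for c in chars.values() if c in _FULL}
        if len(observed) < 2:
            continue
        n_var += 1
        allele_excess += len(observed) - 1
        score += _fitch_column(tree, chars)
    h = score - (allele_excess if excess_mode == "lower_bound" else n_var)
    return ParsimonyResult(n_var, allele_excess, score, h)


def _fitch_column(tree, chars: Mapping[str, str]) -> int:
    changes = 0
    sets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            c = chars[nd.taxon.label]
            sets[nd] = frozenset((c,)) if c in _FULL else _FULL
        else:
            s = None
            for child in nd.child_nodes():
                if s is None:
                    s = sets[child]
                else:
                    inter = s & sets[child]
                    if inter:
                        s = inter
                    else:
                        s = s | sets[child]
                        changes += 1
            sets[nd] = s
    return changes


# ----------------------------------------------------------------------
@dataclass
class AlignmentBlock:
    """One aligned segment of a contig on the target (0-based half-open)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tstart: int
    tend: int

    def __post_init__(self) -> None:
        if not (self.qstart < self.qend and self.tstart < self.tend):
            raise ValueError("block intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentBlock(
            r.qname, int(r.qlen), int(r.qstart), int(r.qend), r.strand,
            r.tname, int(r.tstart), int(r.tend),
        )
        for r in df.itertuples()
    ]


@dataclass
class BreakpointCall:
    qname: str
    verdict: str  # supports_inversion | rejects_inversion | uninformative
    intervals: list[tuple[int, int]] = field(default_factory=list)
    evidence: list[AlignmentBlock] = field(default_factory=list)
    note: str | None = None


def _near(x: int, boundary: int, near_dist: int) -> bool:
    return abs(x - boundary) <= near_dist


def classify_contig_breakpoints(
    blocks: Sequence[AlignmentBlock],
    region: tuple[int, int],
    near_dist: int = 100_000,
    span_margin: int = 10_000,
) -> BreakpointCall:
    """Classify one contig's alignment blocks against a candidate inversion.

    supports_inversion: two blocks lie within ``near_dist`` of opposite
    region boundaries, exactly one of them inside the region, with opposite
    strands and compatible (near-adjacent, non-overlapping beyond
    ``span_margin``) query coordinates. The reported breakpoint intervals
    bracket each boundary between the block's inner target end and the
    boundary itself.

    rejects_inversion: a single block spans a boundary by at least
    ``span_margin`` on both sides (colinear sequence across the putative
    breakpoint).

    Anything else, including blocks on different target sequences, is
    uninformative.
    """
    if not blocks:
        return BreakpointCall("", "uninformative", note="no blocks")
    qname = blocks[0].qname
    if len({b.tname for b in blocks}) > 1:
        return BreakpointCall(qname, "uninformative", note="blocks on different targets")
    s, e = region

    for b in blocks:
        for boundary in (s, e):
            if b.tstart <= boundary - span_margin and b.tend >= boundary + span_margin:
                return BreakpointCall(
                    qname, "rejects_inversion",
                    intervals=[(boundary, boundary)], evidence=[b],
                    note=f"block spans boundary {boundary}",
                )

    def inside(b):
        return s <= b.tstart and b.tend <= e

    def outside(b):
        return b.tend <= s or b.tstart >= e

    for i in range(len(blocks)):
        for j in range(len(blocks)):
            if i == j:
                continue
            bi, bo = blocks[i], blocks[j]
            if not (inside(bi) and outside(bo)):
                continue
            if bi.strand == bo.strand:
                continue
            # query adjacency: non-overlapping, gap bounded by span_margin
            gap = max(bi.qstart, bo.qstart) - min(bi.qend, bo.qend)
            overlap = min(bi.qend, bo.qend) - max(bi.qstart, bo.qstart)
            if gap > span_margin or overlap > span_margin:
                continue
            # the two blocks must sit near opposite boundaries
            near_in = [b for b in (s, e) if _near(bi.tstart, b, near_dist) or _near(bi.tend, b, near_dist)]
            near_out = [b for b in (s, e) if _near(bo.tstart, b, near_dist) or _near(bo.tend, b, near_dist)]
            pairs = [(x, y) for x in near_in for y in near_out if x != y]
            if not pairs:
                continue
            b_in, b_out = pairs[0]
            iv_in = (min(bi.tstart if b_in == s else bi.tend, b_in),
                     max(bi.tstart if b_in == s else bi.tend, b_in))
            iv_out = (min(bo.tend if b_out == s else bo.tstart, b_out),
                      max(bo.tend if b_out == s else bo.tstart, b_out))
            return BreakpointCall(
                qname, "supports_inversion",
                intervals=sorted([iv_in, iv_out]), evidence=[bi, bo],
            )
    return BreakpointCall(qname, "uninformative")
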