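"""Synthetic supergene panels with known ground truth.

The generator emulates the statistical structure that the downstream
analyses assume, without running a full coalescent:

* two inversion arrangements ("A" = ancestral, "B" = derived) that are
  deeply diverged inside the inversion interval and panmictic outside it;
* several populations per arrangement, with allele frequencies drawn from a
  hierarchical Balding-Nichols model (species root -> arrangement group ->
  population) over a U-shaped Beta(0.2, 0.2) root spectrum, so that
  same-arrangement populations share drift;
* fixed "diagnostic" differences between the arrangement founders, in
  complete association with the arrangement;
* an outgroup haplotype for polarization;
* short gene-conversion tracts (50-1,000 bp) copied between arrangements
  with GC-biased mismatch resolution, and optionally one long
  double-crossover tract carried heterozygously by designated individuals;
* per-genotype read depth and quality plus random missingness.

Every operation is deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

BASES = np.array(["A", "C", "G", "T"], dtype=object)
_GC_CODES = frozenset((1, 2))  # C, G

OUTGROUP_SAMPLE = "outgroup"
CHROM = "LG_sim"


# ----------------------------------------------------------------------
@dataclass
class DcTract:
    """A designed double-crossover tract: recipients carry it heterozygously."""

    recipients: tuple[str, ...]
    start: int
    length: int


@dataclass
class SimConfig:
    """Parameters of a synthetic supergene panel.

    The defaults define a desk-scale geometry: a 2 Mb chromosome with a 1 Mb
    inversion, three populations of ten diploids (two ancestral-arrangement,
    one derived), and enough founder divergence for ~5,000 diagnostic sites.
    """

    genome_length: int = 2_000_000
    inversion: tuple[int, int] = (500_000, 1_500_000)
    arrangement_assignment: dict = field(
        default_factory=lambda: {"pop1": "ancestral", "pop2": "ancestral", "pop3": "derived"}
    )
    samples_per_population: int = 10
    mu_sim: float = 1.25e-8  # substitutions / bp / generation
    t_inv: int = 200_000  # generations since the arrangement split
    t_pop: int = 50_000  # generations since population splits
    d_out: float = 0.005  # outgroup-to-ingroup per-site divergence
    gc_base: float = 0.5  # base-composition GC fraction
    poly_density: float = 0.002  # polymorphic sites per bp
    # within-inversion polymorphism relative to outside; the inversion origin
    # acts as a severe bottleneck on the derived arrangement and suppressed
    # recombination further depresses within-arrangement diversity
    inside_poly_factor: float = 1.0
    beta_shape: float = 0.2  # root allele-frequency spectrum Beta(a, a)
    fst_pop: float = 0.05  # population-level drift (Balding-Nichols F)
    fst_group: float = 0.2  # arrangement-group drift
    conversion_tracts: int = 0  # tracts per recipient haplotype
    tract_length_range: tuple[int, int] = (50, 1000)
    gc_bias: float = 0.68  # P(resolve a GC/AT conversion mismatch toward G/C)
    conversion_recipients: tuple[str, ...] = ()
    dc_tract: Optional[DcTract] = None
    mean_depth: float = 20.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.inversion
        if not (0 <= s < e <= self.genome_length):
            raise ValueError("inversion interval must lie within the genome")
        if self.t_pop >= self.t_inv:
            raise ValueError("t_pop must be smaller than t_inv")
        lo, hi = self.tract_length_range
        if not (0 < lo <= hi):
            raise ValueError("tract_length_range must satisfy 0 < min <= max")
        if not 0 <= self.gc_bias <= 1:
            raise ValueError("gc_bias must be in [0, 1]")
        for pop, arr in self.arrangement_assignment.items():
            if arr not in ("ancestral", "derived", "mixed"):
                raise ValueError(f"unknown arrangement {arr!r} for population {pop!r}")

    @property
    def populations(self) -> list[str]:
        return list(self.arrangement_assignment)

    def sample_names(self) -> list[str]:
        return [
            f"{pop}_{i + 1}"
            for pop in self.populations
            for i in range(self.samples_per_population)
        ]


@dataclass
class TractRecord:
    sample: str
    hap: int
    kind: str  # "conversion" | "double_crossover"
    start: int
    end: int
    donor_arrangement: str
    # (pos, donor_base, recipient_base, accepted) per diagnostic mismatch
    outcomes: list[tuple[int, str, str, bool]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(1 for o in self.outcomes if o[3])


@dataclass
class TruthTable:
    """Simulator ground truth for parameter-recovery tests."""

    inversion: tuple[int, int]
    arrangement: dict  # (sample, hap) -> "A" | "B"
    diagnostic_pos: np.ndarray  # 1-based positions of founder-fixed differences
    diagnostic_carrier: np.ndarray  # "A"/"B": arrangement carrying the derived allele
    tracts: list[TractRecord] = field(default_factory=list)
    _ancestral_seq: np.ndarray | None = None  # base codes 0..3
    _site_kind: dict | None = None  # pos -> "diagnostic"|"polymorphic"|"outgroup"
    _site_alt_code: dict | None = None

    def haplotypes_of(self, arrangement: str) -> list[tuple[str, int]]:
        return [k for k, v in self.arrangement.items() if v == arrangement]

    def founder_sequence(self, which: str) -> str:
        """Full sequence of 'reference' (= ancestor), 'A', 'B' or 'outgroup'."""
        if self._ancestral_seq is None:
            raise ValueError("truth table does not carry sequences")
        seq = self._ancestral_seq.copy()
        if which == "reference":
            pass
        elif which in ("A", "B"):
            for pos, carrier in zip(self.diagnostic_pos, self.diagnostic_carrier):
                if carrier == which:
                    seq[pos - 1] = self._site_alt_code[int(pos)]
        elif which == OUTGROUP_SAMPLE:
            for pos, kind in self._site_kind.items():
                if kind == "outgroup":
                    seq[pos - 1] = self._site_alt_code[pos]
        else:
            raise ValueError(f"unknown sequence {which!r}")
        return "".join(BASES[seq])


# ----------------------------------------------------------------------
def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Draw daughter frequencies around p with drift strength f."""
    if f <= 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def _haplotype_arrangements(config: SimConfig) -> np.ndarray:
    """Arrangement code per ingroup haplotype (0 = A/ancestral, 1 = B/derived).

    Mixed populations are split into homokaryotypes: the first half of the
    individuals carry A/A, the rest B/B.
    """
    codes = []
    for pop in config.populations:
        arr = config.arrangement_assignment[pop]
        n = config.samples_per_population
        for i in range(n):
            if arr == "ancestral":
                codes += [0, 0]
            elif arr == "derived":
                codes += [1, 1]
            else:  # mixed: homokaryotypes, half and half
                codes += [0, 0] if i < (n + 1) // 2 else [1, 1]
    return np.array(codes, dtype=np.int8)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Generate a genotype panel plus its ground truth.

    Raises ``ValueError`` when ``mu_sim * t_inv`` is too small to produce any
    diagnostic site (the supergene would be undetectable by construction).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    L = config.genome_length
    inv0, inv1 = config.inversion

    gc = config.gc_base
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    anc = rng.choice(4, size=L, p=probs).astype(np.uint8)

    # --- founder (diagnostic) differences inside the inversion ------------
    n_diag = rng.poisson(2 * config.mu_sim * config.t_inv * (inv1 - inv0))
    if n_diag == 0:
        raise ValueError(
            "zero diagnostic sites: mu_sim * t_inv is too small for the "
            "arrangement founders to differ"
        )
    diag_pos = np.sort(rng.choice(np.arange(inv0, inv1), size=n_diag, replace=False)) + 1
    diag_carrier = np.where(rng.random(n_diag) < 0.5, "A", "B").astype(object)

    # --- polymorphic sites -------------------------------------------------
    n_poly = rng.poisson(config.poly_density * L)
    taken = set(diag_pos.tolist())
    cand = rng.choice(L, size=min(L, int(n_poly * 1.2) + 10), replace=False) + 1
    poly_pos = np.sort(np.array([p for p in cand if p not in taken][:n_poly], dtype=np.int64))
    if config.inside_poly_factor < 1.0 and len(poly_pos):
        in_inv = (poly_pos > inv0) & (poly_pos <= inv1)
        keep = ~in_inv | (rng.random(len(poly_pos)) < config.inside_poly_factor)
        poly_pos = poly_pos[keep]
    taken.update(poly_pos.tolist())

    # --- outgroup substitutions --------------------------------------------
    n_out = rng.poisson(config.d_out * L)
    cand = rng.choice(L, size=min(L, int(n_out * 1.2) + 10), replace=False) + 1
    out_pos = np.sort(np.array([p for p in cand if p not in taken][:n_out], dtype=np.int64))

    # --- haplotype alleles --------------------------------------------------
    hap_arr = _haplotype_arrangements(config)
    n_hap = hap_arr.size
    samples = config.sample_names()

    diag_alleles = (hap_arr[None, :] == np.where(diag_carrier == "A", 0, 1)[:, None].astype(np.int8)).astype(np.int8)

    poly_alleles = np.zeros((len(poly_pos), n_hap), dtype=np.int8)
    if len(poly_pos):
        inside = (poly_pos > inv0) & (poly_pos <= inv1)
        bg = rng.integers(0, 2, size=len(poly_pos)).astype(np.int8)  # background arr inside
        p0 = np.clip(
            rng.beta(config.beta_shape, config.beta_shape, size=len(poly_pos)), 0.01, 0.99
        )
        group_freq = {}
        for grp in ("ancestral", "derived"):
            if any(a == grp for a in config.arrangement_assignment.values()):
                group_freq[grp] = _balding_nichols(rng, p0, config.fst_group)
        col = 0
        for pop in config.populations:
            arr = config.arrangement_assignment[pop]
            idx = np.arange(col, col + 2 * config.samples_per_population)
            col += 2 * config.samples_per_population
            base = group_freq.get(arr, p0)
            p_pop = _balding_nichols(rng, base, config.fst_pop)
            u = rng.random((len(poly_pos), idx.size))
            carriers = u < p_pop[:, None]
            allowed = np.ones_like(carriers)
            allowed[inside] = hap_arr[idx][None, :] == bg[inside][:, None]
            poly_alleles[:, idx] = carriers & allowed

    out_alleles = np.zeros((len(out_pos), n_hap), dtype=np.int8)

    # --- assemble site table, genome-sorted ---------------------------------
    pos = np.concatenate([diag_pos, poly_pos, out_pos])
    kind = np.concatenate(
        [
            np.full(len(diag_pos), "diagnostic", dtype=object),
            np.full(len(poly_pos), "polymorphic", dtype=object),
            np.full(len(out_pos), "outgroup", dtype=object),
        ]
    )
    alleles = np.concatenate([diag_alleles, poly_alleles, out_alleles], axis=0)
    order = np.argsort(pos)
    pos, kind, alleles = pos[order], kind[order], alleles[order]

    n_sites = len(pos)
    ref_code = anc[pos - 1]
    shift = rng.integers(1, 4, size=n_sites).astype(np.uint8)
    alt_code = (ref_code + shift) % 4

    # outgroup diploid: homozygous alt at its own substitutions, ref elsewhere
    og_allele = (kind == "outgroup").astype(np.int8)

    n_ind = n_hap // 2 + 1
    gt = np.empty((n_sites, n_ind, 2), dtype=np.int8)
    gt[:, : n_hap // 2, 0] = alleles[:, 0::2]
    gt[:, : n_hap // 2, 1] = alleles[:, 1::2]
    gt[:, -1, 0] = og_allele
    gt[:, -1, 1] = og_allele

    dp = rng.poisson(config.mean_depth, size=(n_sites, n_ind)).astype(np.int32)
    gq = np.where(dp >= 4, 99, 10).astype(np.int32)
    if config.missing_rate > 0:
        miss = rng.random((n_sites, n_ind)) < config.missing_rate
        gt[miss] = MISSING

    gm = GenotypeMatrix(
        samples=samples + [OUTGROUP_SAMPLE],
        chrom=np.full(n_sites, CHROM, dtype=object),
        pos=pos,
        ref=BASES[ref_code],
        alt=[(str(BASES[c]),) for c in alt_code],
        gt=gt,
        dp=dp,
        gq=gq,
    )

    arrangement = {}
    for j, name in enumerate(samples):
        arrangement[(name, 0)] = "AB"[hap_arr[2 * j]]
        arrangement[(name, 1)] = "AB"[hap_arr[2 * j + 1]]
    truth = TruthTable(
        inversion=config.inversion,
        arrangement=arrangement,
        diagnostic_pos=diag_pos,
        diagnostic_carrier=diag_carrier,
        _ancestral_seq=anc,
        _site_kind={int(p): str(k) for p, k in zip(pos, kind)},
        _site_alt_code={int(p): int(c) for p, c in zip(pos, alt_code)},
    )
    return gm, truth


# ----------------------------------------------------------------------
def _site_lookup(gm: GenotypeMatrix, positions: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(gm.pos, positions)
    ok = (idx < gm.n_sites) & (gm.pos[np.minimum(idx, gm.n_sites - 1)] == positions)
    if not ok.all():
        raise ValueError("positions missing from the genotype matrix")
    return idx


def _hap_allele_set(gm, site_idx, sample_idx, hap, allele):
    a, b = gm.gt[site_idx, sample_idx]
    if a == MISSING or b == MISSING:
        return  # genotype unobserved; the underlying copy is not visible
    gm.gt[site_idx, sample_idx, hap] = allele


def implant_conversion_tracts(
    panel: GenotypeMatrix, truth: TruthTable, config: SimConfig
) -> tuple[GenotypeMatrix, TruthTable]:
    """Copy short donor tracts between arrangements with GC-biased acceptance.

    For each recipient haplotype, ``config.conversion_tracts`` tracts are
    drawn with uniform start inside the inversion and length uniform in
    ``tract_length_range``. At each diagnostic site inside a tract the donor
    (opposite-arrangement) allele replaces the recipient allele with
    probability ``gc_bias`` when the donor base is G/C and the recipient base
    is A/T, probability ``1 - gc_bias`` in the reverse case, and 0.5 when the
    mismatch is GC-conservative.
    """
    if config.conversion_tracts == 0 or not config.conversion_recipients:
        return panel, truth
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    inv0, inv1 = truth.inversion
    lmin, lmax = config.tract_length_range
    diag_pos = truth.diagnostic_pos
    diag_idx = _site_lookup(panel, diag_pos)
    sample_idx = {s: i for i, s in enumerate(panel.samples)}

    arrs = set(truth.arrangement.values())
    for recipient in config.conversion_recipients:
        if recipient not in sample_idx:
            raise KeyError(f"recipient {recipient!r} not in panel")
        for hap in (0, 1):
            rec_arr = truth.arrangement[(recipient, hap)]
            donor_arr = "B" if rec_arr == "A" else "A"
            if donor_arr not in arrs:
                raise ValueError(
                    f"no {donor_arr}-arrangement haplotypes available as donors"
                )
            for _ in range(config.conversion_tracts):
                length = int(rng.integers(lmin, lmax + 1))
                start = int(rng.integers(inv0, max(inv0 + 1, inv1 - length)))
                end = start + length
                rec = TractRecord(recipient, hap, "conversion", start, end, donor_arr)
                lo = np.searchsorted(diag_pos, start + 1)
                hi = np.searchsorted(diag_pos, end, side="right")
                for k in range(lo, hi):
                    donor_allele = 1 if truth.diagnostic_carrier[k] == donor_arr else 0
                    rec_allele = 1 - donor_allele
                    si = diag_idx[k]
                    donor_base = panel.alt[si][0] if donor_allele else panel.ref[si]
                    rec_base = panel.alt[si][0] if rec_allele else panel.ref[si]
                    d_gc = donor_base in "GC"
                    r_gc = rec_base in "GC"
                    if d_gc and not r_gc:
                        p_accept = config.gc_bias
                    elif r_gc and not d_gc:
                        p_accept = 1 - config.gc_bias
                    else:
                        p_accept = 0.5
                    accepted = bool(rng.random() < p_accept)
                    rec.outcomes.append((int(diag_pos[k]), donor_base, rec_base, accepted))
                    if accepted:
                        _hap_allele_set(panel, si, sample_idx[recipient], hap, donor_allele)
                truth.tracts.append(rec)
    return panel, truth


def implant_double_crossover(
    panel: GenotypeMatrix, truth: TruthTable, config: SimConfig
) -> tuple[GenotypeMatrix, TruthTable]:
    """Give one haplotype per recipient the donor alleles across a long tract.

    Recipients become heterozygous at every diagnostic site in
    ``[start, start + length)``. A zero-length tract leaves the panel
    unchanged.
    """
    dc = config.dc_tract
    if dc is None:
        return panel, truth
    if dc.length == 0:
        return panel, truth
    inv0, inv1 = truth.inversion
    if not (inv0 <= dc.start and dc.start + dc.length <= inv1):
        raise ValueError("double-crossover tract must lie inside the inversion")
    diag_pos = truth.diagnostic_pos
    diag_idx = _site_lookup(panel, diag_pos)
    sample_idx = {s: i for i, s in enumerate(panel.samples)}
    hap = 1
    lo = np.searchsorted(diag_pos, dc.start + 1)
    hi = np.searchsorted(diag_pos, dc.start + dc.length, side="right")
    for recipient in dc.recipients:
        if recipient not in sample_idx:
            raise KeyError(f"recipient {recipient!r} not in panel")
        rec_arr = truth.arrangement[(recipient, hap)]
        donor_arr = "B" if rec_arr == "A" else "A"
        rec = TractRecord(
            recipient, hap, "double_crossover", dc.start, dc.start + dc.length, donor_arr
        )
        for k in range(lo, hi):
            donor_allele = 1 if truth.diagnostic_carrier[k] == donor_arr else 0
            si = diag_idx[k]
            donor_base = panel.alt[si][0] if donor_allele else panel.ref[si]
            rec_base = panel.alt[si][0] if donor_allele == 0 else panel.ref[si]
            rec.outcomes.append((int(diag_pos[k]), donor_base, rec_base, True))
            _hap_allele_set(panel, si, sample_idx[recipient], hap, donor_allele)
        truth.tracts.append(rec)
    return panel, truth


# ----------------------------------------------------------------------
def simulate_contig_blocks(
    config: SimConfig,
    seed: int = 0,
    mean_contig: int = 50_000,
    carries_inversion: bool = True,
):
    """Fragment a donor genome into contigs and map them onto the reference.

    The donor carries the inversion when ``carries_inversion`` is true, so
    contigs straddling a breakpoint produce two alignment blocks of opposite
    strand that map near opposite inversion boundaries. Returns
    ``(blocks, (left_breakpoint, right_breakpoint))`` where blocks are
    :class:`~supergene_kit.assembly_compare.AlignmentBlock` records.
    """
    from .assembly_compare import AlignmentBlock

    if mean_contig > config.genome_length:
        raise ValueError("mean contig length exceeds the genome")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    L = config.genome_length
    s, e = config.inversion

    cuts = [0]
    while cuts[-1] < L:
        cuts.append(min(L, cuts[-1] + int(rng.uniform(0.5, 1.5) * mean_contig)))
    blocks = []

    def _map_part(qname, qlen, q0, q1, d0, d1):
        """Map donor interval [d0, d1) (query [q0, q1)) onto the reference."""
        if not carries_inversion or d1 <= s or d0 >= e:
            return [AlignmentBlock(qname, qlen, q0, q1, "+", "ref", d0, d1)]
        if d0 >= s and d1 <= e:  # fully inside: reverse complement
            return [AlignmentBlock(qname, qlen, q0, q1, "-", "ref", s + e - d1, s + e - d0)]
        parts = []
        if d0 < s:
            parts += _map_part(qname, qlen, q0, q0 + (s - d0), d0, s)
            parts += _map_part(qname, qlen, q0 + (s - d0), q1, s, d1)
        else:  # straddles the right breakpoint
            parts += _map_part(qname, qlen, q0, q0 + (e - d0), d0, e)
            parts += _map_part(qname, qlen, q0 + (e - d0), q1, e, d1)
        return parts

    for k in range(len(cuts) - 1):
        c0, c1 = cuts[k], cuts[k + 1]
        blocks += _map_part(f"contig_{k:04d}", c1 - c0, 0, c1 - c0, c0, c1)
    return blocks, (s, e)


def write_blocks_tsv(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("qname\tqlen\tqstart\tqend\tstrand\ttname\ttstart\ttend\n")
        for b in blocks:
            fh.write(
                f"{b.qname}\t{b.qlen}\t{b.qstart}\t{b.qend}\t{b.strand}\t"
                f"{b.tname}\t{b.tstart}\t{b.tend}\n"
            )


# ----------------------------------------------------------------------
def simulate_window_trees(
    population_order: Sequence[str],
    background_times: Sequence[float],
    supergene_times: Sequence[float],
    n_windows: int,
    window_bp: int = 250_000,
    supergene_interval: tuple[int, int] | None = None,
    n_samples: int = 100,
    jitter_sd: float = 0.1,
    outgroup: str | None = None,
    seed: int = 0,
):
    """Per-window ultrametric population trees plus jittered posterior samples.

    Windows tile ``[0, n_windows * window_bp)``. Windows overlapping
    ``supergene_interval`` use ``supergene_times`` as the adjacent divergence
    times on the ladderized population order; the rest use
    ``background_times``. Posterior samples perturb node heights with
    multiplicative lognormal noise (sd ``jitter_sd``), preserving
    ultrametricity; ``jitter_sd=0`` reproduces the consensus exactly.
    """
    from .profiles import WindowTreeSet, reconstruct_tree

    if len(background_times) != len(population_order) - 1 or len(supergene_times) != len(
        population_order
    ) - 1:
        raise ValueError("need exactly n_populations - 1 adjacent divergence times")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    out = []
    for w in range(n_windows):
        lo, hi = w * window_bp, (w + 1) * window_bp
        in_sg = supergene_interval is not None and lo < supergene_interval[1] and hi > supergene_interval[0]
        times = supergene_times if in_sg else background_times
        base = reconstruct_tree(list(population_order), list(times))
        supports = rng.uniform(0.85, 1.0, size=max(1, len(population_order) - 1))
        consensus = _newick_with_jitter(base, 0.0, rng, outgroup, supports=supports)
        samples = [
            _newick_with_jitter(base, jitter_sd, rng, outgroup) for _ in range(n_samples)
        ]
        out.append(
            WindowTreeSet(
                window=(lo, hi),
                consensus_newick=consensus,
                sample_newicks=samples,
                n_usable_snps=int(rng.integers(400, 900)),
                min_ess=float(rng.uniform(150, 800)),
            )
        )
    return out


def _newick_with_jitter(tree, sd, rng, outgroup=None, supports=None):
    """Render a dendropy ultrametric tree with jittered node heights."""
    import dendropy

    t = tree.clone(depth=1)
    # node heights from leaf depth zero upward
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._h = 0.0
        else:
            child_max = max(c._h + (c.edge.length or 0.0) for c in nd.child_nodes())
            nd._h = child_max
    if sd > 0:
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                continue
            nd._h = nd._h * float(np.exp(rng.normal(0.0, sd)))
        for nd in t.postorder_node_iter():  # restore parent > child
            if nd.is_leaf():
                continue
            nd._h = max(nd._h, max(c._h for c in nd.child_nodes()) + 1e-12)
    i = 0
    for nd in t.postorder_node_iter():
        for c in nd.child_nodes():
            c.edge.length = nd._h - c._h
        if not nd.is_leaf() and supports is not None:
            nd.label = f"{supports[min(i, len(supports) - 1)]:.4f}"
            i += 1
    root_h = t.seed_node._h
    core = t.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
    if outgroup is not None:
        og_h = 3.0 * max(root_h, 1e-9)
        return f"({core}:{og_h - root_h},{outgroup}:{og_h});"
    return core + ";"


# ----------------------------------------------------------------------
def write_outputs(panel: GenotypeMatrix, truth: TruthTable, outdir) -> dict:
    """Write the panel VCF, founder/outgroup FASTA and truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "fasta": os.path.join(outdir, "founders.fasta"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    panel.to_vcf(paths["vcf"])
    with open(paths["fasta"], "w") as fh:
        for name in ("reference", "A", "B", OUTGROUP_SAMPLE):
            fh.write(f">{name}\n")
            seq = truth.founder_sequence(name)
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("record\tsample\thap\tvalue\tstart\tend\tdonor\tn_events\tn_accepted\n")
        for (sample, hap), arr in truth.arrangement.items():
            fh.write(f"arrangement\t{sample}\t{hap}\t{arr}\t.\t.\t.\t.\t.\n")
        for tr in truth.tracts:
            fh.write(
                f"tract\t{tr.sample}\t{tr.hap}\t{tr.kind}\t{tr.start}\t{tr.end}\t"
                f"{tr.donor_arrangement}\t{len(tr.outcomes)}\t{tr.n_accepted}\n"
            )
    return paths
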