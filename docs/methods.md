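# Methods

This note documents the models and procedures implemented in supergene-kit,
the defaults that matter, the design choices made where the design was
genuinely open, and what the simulation-based validation does and does not
demonstrate.

## The synthetic supergene panel (`simdata`)

The simulator is founder-based, not coalescent: it generates exactly the
statistical structure the downstream statistics consume (LD contrast,
polarized site patterns, tract structure) at a fraction of the cost, and its
ground truth is exact. Default geometry is desk-scale: a 2 Mb chromosome
with a 1 Mb inversion at [0.5, 1.5) Mb, three populations of ten diploids
(pop1 and pop2 carrying the ancestral arrangement, pop3 the derived one)
plus one outgroup diploid.

Generative recipe:

1. An ancestral sequence with GC fraction `gc_base` (default 0.5).
2. Arrangement founders A and B differ at Poisson(2·`mu_sim`·`t_inv`·L_inv)
   "diagnostic" sites sprinkled uniformly inside the inversion (defaults
   `mu_sim` = 1.25e-8 /bp/generation, `t_inv` = 200,000 generations, hence
   ≈5,000 diagnostic sites). The substituted base is assigned to the A or B
   lineage with equal probability; diagnostic alleles are carried in
   complete association with the arrangement (pairwise R² = 1 among
   haplotypes).
3. Polymorphic sites at density `poly_density` (default 0.002 /bp). Allele
   frequencies follow a hierarchical Balding–Nichols model: a root frequency
   from Beta(0.2, 0.2) (U-shaped, neutral-like), an arrangement-group
   frequency drawn around it with drift `fst_group` = 0.2, and per-population
   frequencies with drift `fst_pop` = 0.05. The hierarchy makes
   same-arrangement populations share drift, which is what gives BBAA its
   expected dominance among pattern sums — without it all three pattern sums
   are exchangeable and the D_BBAA orientation rule (and the BBAA reference
   set of the GC test) would be arbitrary. Outside the inversion carriers
   are assigned independently per haplotype (free recombination, low LD);
   inside, each site segregates on one arrangement background only.
   `inside_poly_factor` (default 1) scales the within-inversion polymorphic
   density; the inversion origin acts as a severe bottleneck on the derived
   arrangement and suppressed recombination further depresses
   within-arrangement diversity, so values < 1 are the realistic direction.
4. The outgroup haplotype adds Poisson(`d_out`·L) substitutions
   (`d_out` = 0.005).
5. Per-genotype DP ~ Poisson(`mean_depth` = 20), GQ high (99) where DP ≥ 4,
   genotypes set missing at `missing_rate` = 0.02.

Gene-conversion tracts start uniformly inside the inversion with length
Uniform(50, 1000) bp — the length scale of non-crossover conversion — and
replace recipient alleles at diagnostic sites with the donor-arrangement
allele with probability `b` when the donor base is G/C against an A/T
recipient, `1−b` in the reverse case, and 0.5 for GC-conservative
mismatches. `b` defaults to 0.68, a typical transmission bias for GC-biased
gene conversion; the direction, not the magnitude, is what the literature
constrains, so `b` is a free parameter. The double-crossover tract gives one
haplotype of each designated recipient the donor alleles at every diagnostic
site in a configurable interval (default length 27.5 kb — one tenth of the
~275 kb empirical scale, keeping runtimes in seconds), leaving recipients
heterozygous across it.

What the simulator does **not** emulate: recombination gradients and LD
decay, selection, gapped/structural variation, read-level artifacts,
multi-allelic sites, and realistic demography. Passing recovery tests on
these panels therefore shows the statistics behave correctly under their own
assumptions, not that real data meet those assumptions.

## Filters (`vcf_filters`)

Canonical order: genotype mask (GQ < 20, DP < 3 or DP > 80 → missing, all
strict), indel-proximity filter, site filters (missing fraction > 0.8 or
minor allele count < 20 dropped, strict), restriction to biallelic variable
sites. The indel-proximity window is 10 bp for indels of 5 bp or longer, 5
for 3–4 bp, 3 for 2 bp and 2 for 1 bp; distance is measured to the indel's
reference footprint `[pos, pos+len(ref)−1]` (the anchor point is otherwise
underdetermined), indel length is `max(len(ref), len(longest alt)) − 1`, and
all indels are removed afterwards. Upstream caller-level hard filters (FS,
QD, MQ, rank sums) are assumed pre-applied; this package consumes VCFs, not
BAMs.

## LD delimitation (`popgen_stats`)

R² is the squared Pearson correlation of unphased alt-dosages over samples
non-missing at both sites (pairs with < 2 informative samples or zero
variance are omitted), computed for pairs closer than 250 kb with
mask-aware chunked matrix products. The linkage span S of a SNP is the
summed distance to partners with R² strictly above 0.8. Boundary calling —
a visual judgement in the original analysis — is made reproducible as:
centred rolling median of S over 25 SNPs, two-means classification of
log1p(smoothed S) (deterministic extreme-value initialization), maximal
high-class runs tolerating ≤ 10 consecutive low-class SNPs. On default
panels the called boundaries land within ≤ 5 SNP positions of the outermost
diagnostic sites (measured over 20 seeds).

π uses a caller-supplied accessible-length denominator (masking-aware), the
unbiased per-site heterozygosity 2p(1−p)·n/(n−1). F_ST is Hudson's
estimator aggregated as ratio of sums within windows; d_XY sums
`p_A(1−p_B) + p_B(1−p_A)`. An independent check against an msprime
two-population split model confirms the Hudson estimator approaches
T/(T+2N).

## Gene-flux statistics (`dstats`, `conversion_gc`)

Sites are polarized on the outgroup (its allele is ancestral; sites with a
missing, heterozygous or polymorphic outgroup are dropped), and the weights
are the standard polarized-frequency products with the outgroup treated as
fixed ancestral (no (1−p₄) term). Jackknife blocks are contiguous and equal
in SNP count — the natural reading of "blocks of equal size" for site-based
sums. The BBAA orientation permutes trio roles so the BBAA sum is largest
(ties broken by label order), then orders P1/P2 so D ≥ 0; the fix
orientation takes the sister pair from a supplied topology and leaves the
sign free. f_dM follows the published donor-substitution definition exactly
(donor = argmax derived frequency substituted for both P2 and P3, or for P1
and P3 with negated sign when p₂ < p₁); an independent site-wise evaluation
backs it in the tests. D_tree counts, per rooted gene tree, which trio pair
is sisters (MRCA excluding the third taxon; polytomies count no pair), with
frequency ties broken lexicographically.

The GC test takes "GC content of a site" to be the indicator that the
shared derived allele is G or C — the quantity gBGC acts on directly; local
sequence-context GC is out of scope. Sites are hard-classified by their
strictly largest pattern weight, and the ABBA set is compared against the
BBAA set with a one-sided Welch t-test (unequal variances; the degrees of
freedom of the empirical analysis are consistent with Welch).

## Painting (`painting`)

Informative sites require < 10% missing genotypes over the two groups and
allele-frequency contrast ≥ 0.9 / ≤ 0.1 (called alleles only). Tract
detection reports maximal runs of consecutive informative sites at which
*all* focal individuals are heterozygous; `min_run` = 5 suppresses
single-site het noise (no empirical minimum exists to borrow), and
`max_miss_in_run` = 0 by default with endpoints always trimmed to jointly
heterozygous sites. Runs are joint over focal individuals because the
empirical signature of interest is a tract shared by multiple carriers.

## Profiles (`profiles`)

Window SNP selection: greedy left-to-right thinning at ≥ 50 bp spacing in
250 kb windows, dropping windows with < 500 SNPs and downsampling those
above 1,000 uniformly at random (seeded). Window QC drops windows with
< 300 usable SNPs, ESS < 100 or mean internal-node BPP < 0.5 (all strict
"below").

A ladderized ultrametric tree is reduced to its tip order plus the MRCA
heights of adjacent tips. This reduction is lossless: the implied divergence
time of tips i < j is the maximum adjacent time between them, and splitting
recursively at the largest adjacent time (single-linkage clustering of that
matrix) returns the original topology and node heights — verified on random
ultrametric trees to 1e-9. Ladderization orders children by (clade size,
lexicographically smallest descendant) so plots are deterministic; the
round trip is invariant to the tie-break. Trees must be ultrametric within
a relative tolerance of 1e-6 (posterior samples can be slightly off after
parsing); anything worse is an error rather than silently repaired.
Stacked positions are y₁ = 0, y₍k+1₎ = y_k + t_k per window, summarized
over a posterior sample by mean and central 95% interval. The consensus
tree is the default profile source; per-sample profiles are supported.

## Assembly comparison (`assembly_compare`)

The strict consensus keeps a column only when all three alignment methods
present the identical query base; columns gapping the reference are deleted
so reference coordinates are preserved. Windowed divergence is the
uncorrected p-distance over columns informative in both sequences, with the
focal/outgroup ratio left missing below 10,000 informative columns per
100 kb window. Fitch parsimony treats gaps/ambiguity as the full state set;
the hemiplasy excess is H = P − Σ(k_i − 1) against the per-column parsimony
lower bound (for strictly biallelic columns this equals P − n_var, which is
also available). Breakpoint classification: a contig supports an inversion
when two of its blocks lie within 100 kb of opposite region boundaries,
exactly one inside, with opposite strands and near-adjacent query
coordinates; a single block spanning a boundary by ≥ 10 kb on both sides
rejects it. Reported breakpoint intervals bracket each boundary between the
block's inner target end and the boundary; coordinates are 0-based
half-open internally.

## Rates (`rates`)

T_coal = T_div + g·N_anc; μ_year = S/(2·T_coal·G); μ_gen = μ_year·g.
Cross-group substitution counts are means over all cross-group diploid
pairs of per-pair expected allele mismatches, skipping missing genotypes
pairwise. A simulation round trip (founder divergence re-estimated from
cross-arrangement pairwise differences inside the inversion) recovers the
simulated rate within 10%.

## Validation study conditions (`validation`)

Chosen once and fixed:

- **Null calibration**: 100 default panels with `poly_density` = 0.03
  (≥ 50,000 polarized sites each), no gene flux; |Z| > 3 expected in ≲ 0.3
  runs under correct calibration, required in ≤ 5.
- **Gene-flux power**: 150 conversion tracts per recipient haplotype into
  all ten pop2 diploids at b = 0.8 (≈ 3,700 accepted conversions per
  panel). The load is set to emulate a strong empirical gene-flux signal
  (D_BBAA ≈ 0.38–0.45): the block jackknife correctly inflates the SE of a
  spatially clustered signal, so weak tract loads give honest but
  non-significant D even when the GC test already rejects. Joint detection
  (Z > 3 and GC p < 0.05) is required in ≥ 80% of 50 seeds; at b = 0.5 the
  GC test must stay near its nominal 5% level (≤ ~10% observed).
- **Boundary recovery**: 20 default panels, ingroup-only, masked and
  MAC ≥ 5 filtered before LD.
- **Tract recovery**: 27.5 kb tract in [950, 977.5) kb carried by two pop1
  individuals; `missing_rate` = 0 and `inside_poly_factor` = 0, the regime
  in which exact endpoint identity is well-defined (with within-arrangement
  polymorphism inside the inversion, some informative sites are legitimately
  homozygous in the recipients and detection is correct-but-inexact). The
  focal individuals' population is excluded from both frequency groups,
  mirroring the empirical design.

## Known limitations

- The founder-based simulator has no LD decay; boundary-calling accuracy on
  real data, where linkage declines gradually, will be lower than on the
  step-like simulated profiles.
- The frequency-weight D assumes a fixed-ancestral outgroup; a polymorphic
  outgroup frequency term is not implemented.
- Breakpoint intervals assume split alignments end at the true breakpoints;
  alignment trimming noise in real mappers widens them in ways the
  simulator does not model.
- `d_tree` requires rooted trees (or an outgroup to root on); unrooted
  quartet support is out of scope.
- The GC test treats sites as independent; clustered conversion tracts
  violate this mildly, which is conservative for the BBAA reference set but
  can overstate significance for very few, long tracts.
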