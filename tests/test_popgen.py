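"""LD statistics, high-LD delimitation, and diversity/differentiation measures."""

import numpy as np
import pytest

from conftest import build_gm
from supergene_kit.popgen_stats import (
    LdProfile,
    delimit_high_ld,
    dosage_r2,
    ld_span_sum,
    nucleotide_diversity_pi,
    window_fst_dxy,
)


def gm_from_dosages(positions, dosage_columns):
    """Build a diploid matrix whose alt dosages equal the given columns."""
    records = []
    for pos, col in zip(positions, dosage_columns):
        gts = []
        for d in col:
            gts.append((-1, -1) if d is None else ((0, 0), (0, 1), (1, 1))[d])
        records.append((pos, "A", ("G",), gts))
    return build_gm(records)


class TestDosageR2:
    def test_identical_columns_r2_one(self):
        gm = gm_from_dosages([100, 200], [[0, 1, 2, 0], [0, 1, 2, 0]])
        pairs = dosage_r2(gm)
        assert pairs.r2 == pytest.approx([1.0])

    def test_perfect_negative_correlation_r2_one(self):
        gm = gm_from_dosages([100, 200], [[0, 1, 2, 0], [2, 1, 0, 2]])
        assert dosage_r2(gm).r2 == pytest.approx([1.0])

    def test_hand_evaluated_pearson(self):
        x, y = [0, 0, 1, 2], [0, 1, 1, 2]
        # closed-form Pearson on 4 samples as the oracle
        n = 4
        sx, sy = sum(x), sum(y)
        sxx, syy, sxy = sum(a * a for a in x), sum(b * b for b in y), sum(
            a * b for a, b in zip(x, y)
        )
        r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        gm = gm_from_dosages([100, 200], [x, y])
        assert dosage_r2(gm).r2 == pytest.approx([r**2])

    def test_monomorphic_pair_omitted(self):
        gm = gm_from_dosages([100, 200], [[1, 1, 1, 1], [0, 1, 2, 0]])
        pairs = dosage_r2(gm)
        assert len(pairs.r2) == 0 and pairs.n_omitted == 1

    def test_pairwise_missing_handling(self):
        gm = gm_from_dosages([100, 200], [[0, 1, 2, None], [0, 1, 2, 2]])
        assert dosage_r2(gm).r2 == pytest.approx([1.0])

    def test_max_dist_excludes_far_pairs(self):
        gm = gm_from_dosages([100, 300_000], [[0, 1, 2, 0], [0, 1, 2, 0]])
        assert len(dosage_r2(gm).r2) == 0

    def test_allele_coding_swap_invariance(self):
        cols = [[0, 1, 2, 0, 1], [0, 0, 1, 2, 2]]
        gm1 = gm_from_dosages([100, 200], cols)
        gm2 = gm_from_dosages([100, 200], [[2 - d for d in c] for c in cols])
        assert dosage_r2(gm1).r2 == pytest.approx(list(dosage_r2(gm2).r2))


class TestSpanSum:
    def test_single_linked_pair(self):
        prof = LdProfile(pos=np.array([100, 200, 1000]), s=np.zeros(3))
        from supergene_kit.popgen_stats import LinkedPairSet

        pairs = LinkedPairSet(
            pos=prof.pos, i=np.array([0, 0, 1]), j=np.array([1, 2, 2]),
            r2=np.array([0.95, 0.1, 0.2]), max_dist=250_000,
        )
        assert list(ld_span_sum(pairs).s) == [100, 100, 0]

    def test_threshold_is_strict(self):
        from supergene_kit.popgen_stats import LinkedPairSet

        pairs = LinkedPairSet(
            pos=np.array([0, 10]), i=np.array([0]), j=np.array([1]),
            r2=np.array([0.8]), max_dist=250_000,
        )
        assert list(ld_span_sum(pairs, r2_threshold=0.8).s) == [0, 0]

    def test_three_mutually_linked_snps(self):
        from supergene_kit.popgen_stats import LinkedPairSet

        pairs = LinkedPairSet(
            pos=np.array([0, 10, 30]), i=np.array([0, 0, 1]), j=np.array([1, 2, 2]),
            r2=np.array([0.9, 0.9, 0.9]), max_dist=250_000,
        )
        assert list(ld_span_sum(pairs).s) == [40, 30, 50]


class TestDelimit:
    def test_step_profile_recovered(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(1_000_000, 2000, replace=False))
        s = np.where((pos >= 300_000) & (pos < 700_000), 1e6, 0.0)
        prof = LdProfile(pos=pos, s=s)
        (a, b), = delimit_high_ld(prof)
        inside = np.flatnonzero(s > 0)
        assert abs(np.searchsorted(pos, a) - inside[0]) <= 13
        assert abs(np.searchsorted(pos, b - 1) - inside[-1]) <= 13

    def test_uniform_low_profile_empty(self):
        prof = LdProfile(pos=np.arange(100) * 10, s=np.zeros(100))
        assert delimit_high_ld(prof) == []

    def test_too_few_snps_raise(self):
        prof = LdProfile(pos=np.arange(10), s=np.arange(10.0))
        with pytest.raises(ValueError):
            delimit_high_ld(prof, smooth_window=25)


def test_span_inside_inversion_exceeds_outside(default_panel):
    from supergene_kit.vcf_filters import mask_genotypes, site_filters

    cfg, panel, _ = default_panel
    gm = panel.take_samples([s for s in panel.samples if s != "outgroup"])
    gm = site_filters(mask_genotypes(gm), min_mac=5)
    prof = ld_span_sum(dosage_r2(gm))
    inside = (prof.pos > cfg.inversion[0]) & (prof.pos <= cfg.inversion[1])
    assert prof.s[inside].mean() > prof.s[~inside].mean()


class TestPi:
    def test_monomorphic_group_zero(self):
        gm = build_gm([(100, "A", ("G",), [(0, 0), (0, 0)])])
        assert nucleotide_diversity_pi(gm, ["s0", "s1"], 1000) == 0.0

    def test_closed_form_single_site(self):
        # p = 0.5, n = 4 alleles, denominator 1000 bp
        gm = build_gm([(100, "A", ("G",), [(0, 1), (0, 1)])])
        expected = 2 * 0.25 * (4 / 3) / 1000
        assert nucleotide_diversity_pi(gm, ["s0", "s1"], 1000) == pytest.approx(expected)

    def test_allele_label_swap_invariance(self):
        gts = [(0, 1), (1, 1), (0, 0)]
        swapped = [(1, 0), (0, 0), (1, 1)]
        a = nucleotide_diversity_pi(build_gm([(1, "A", ("G",), gts)]), ["s0", "s1", "s2"], 10)
        b = nucleotide_diversity_pi(build_gm([(1, "A", ("G",), swapped)]), ["s0", "s1", "s2"], 10)
        assert a == pytest.approx(b)

    def test_bad_denominator(self):
        gm = build_gm([(100, "A", ("G",), [(0, 1)])])
        with pytest.raises(ValueError):
            nucleotide_diversity_pi(gm, ["s0"], 0)


class TestFstDxy:
    def test_fixed_differences(self):
        gts = [(0, 0)] * 4 + [(1, 1)] * 4
        gm = build_gm([(p, "A", ("G",), gts) for p in (100, 200, 300)])
        df = window_fst_dxy(gm, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                            window=1000)
        assert df.fst.iloc[0] == pytest.approx(1.0)
        assert df.dxy.iloc[0] == pytest.approx(3 / 1000)

    def test_identical_frequencies_zero_fst(self):
        gts = [(0, 1)] * 4 + [(0, 1)] * 4
        gm = build_gm([(100, "A", ("G",), gts)])
        df = window_fst_dxy(gm, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                            window=1000)
        assert abs(df.fst.iloc[0]) < 0.2  # small-sample Hudson correction, not exactly 0

    def test_two_site_hand_example(self):
        # large n approximated by 20 diploids per group
        nA = nB = 20
        a1 = [(0, 1)] * nA           # pA = 0.5
        b1 = [(0, 1)] * nB           # pB = 0.5
        a2 = [(0, 0)] * nA           # pA = 0
        b2 = [(1, 1)] * nB           # pB = 1
        gm = build_gm(
            [(100, "A", ("G",), a1 + b1), (200, "A", ("G",), a2 + b2)],
            samples=[f"a{i}" for i in range(nA)] + [f"b{i}" for i in range(nB)],
        )
        ga, gb = [f"a{i}" for i in range(nA)], [f"b{i}" for i in range(nB)]
        df = window_fst_dxy(gm, ga, gb, window=1000)
        n_al = 2 * nA
        hw_site1 = 2 * 0.25 * n_al / (n_al - 1)  # both groups
        hb_site1 = 0.5
        hb_site2 = 1.0
        fst = 1 - (0.5 * (hw_site1 + hw_site1)) / (hb_site1 + hb_site2)
        assert df.fst.iloc[0] == pytest.approx(fst)
        assert df.dxy.iloc[0] == pytest.approx((hb_site1 + hb_site2) / 1000)

    def test_empty_window_flagged(self):
        gts = [(0, 1)] * 4
        gm = build_gm([(1500, "A", ("G",), gts)])
        df = window_fst_dxy(gm, ["s0", "s1"], ["s2", "s3"], window=1000)
        assert np.isnan(df.fst.iloc[0])  # first window has no site

    def test_overlapping_groups_rejected(self):
        gm = build_gm([(100, "A", ("G",), [(0, 1)] * 4)])
        with pytest.raises(ValueError):
            window_fst_dxy(gm, ["s0", "s1"], ["s1", "s2"])


def test_hudson_fst_matches_split_model_expectation():
    """Independent oracle: msprime two-population split; Hudson F_ST should
    approach T / (T + 2N) (ratio of expected sums) within Monte Carlo error."""
    import msprime

    N, T = 1000, 1000
    demog = msprime.Demography()
    demog.add_population(name="A", initial_size=N)
    demog.add_population(name="B", initial_size=N)
    demog.add_population(name="anc", initial_size=N)
    demog.add_population_split(time=T, derived=["A", "B"], ancestral="anc")
    ts = msprime.sim_ancestry(
        samples={"A": 10, "B": 10}, demography=demog, sequence_length=5e5,
        recombination_rate=1e-8, random_seed=7,
    )
    ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=7)
    geno = ts.genotype_matrix()  # (sites, 40 haplotypes)
    # collapse haplotype pairs into diploid genotype records
    records = []
    for k, site in enumerate(ts.sites()):
        row = geno[k]
        if set(row) - {0, 1}:
            continue
        gts = [(int(row[2 * i]), int(row[2 * i + 1])) for i in range(20)]
        records.append((int(site.position) + 1, "A", ("G",), gts))
    seen = set()
    records = [r for r in records if not (r[0] in seen or seen.add(r[0]))]
    gm = build_gm(records, samples=[f"i{i}" for i in range(20)])
    df = window_fst_dxy(gm, [f"i{i}" for i in range(10)], [f"i{i}" for i in range(10, 20)],
                        window=10_000_000)
    expected = T / (T + 2 * N)
    assert df.fst.iloc[0] == pytest.approx(expected, abs=0.08)
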