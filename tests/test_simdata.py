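"""Generator correctness: determinism, diagnostic-site statistics, tract logic."""

import numpy as np
import pytest
from scipy import stats

from supergene_kit.genotypes import GenotypeMatrix
from supergene_kit.simdata import (
    DcTract,
    SimConfig,
    implant_conversion_tracts,
    implant_double_crossover,
    simulate_contig_blocks,
    simulate_panel,
    simulate_window_trees,
    write_outputs,
)


def test_same_seed_gives_byte_identical_vcf(tmp_path):
    for k in (1, 2):
        cfg = SimConfig(seed=42)
        panel, truth = simulate_panel(cfg)
        write_outputs(panel, truth, tmp_path / f"run{k}")
    assert (tmp_path / "run1" / "panel.vcf").read_bytes() == (
        tmp_path / "run2" / "panel.vcf"
    ).read_bytes()


def test_zero_divergence_raises():
    with pytest.raises(ValueError, match="diagnostic"):
        simulate_panel(SimConfig(seed=0, mu_sim=0.0))


def test_diagnostic_count_matches_poisson_expectation():
    cfg = SimConfig(seed=5)
    _, truth = simulate_panel(cfg)
    expect = 2 * cfg.mu_sim * cfg.t_inv * (cfg.inversion[1] - cfg.inversion[0])
    assert abs(len(truth.diagnostic_pos) - expect) < 4 * np.sqrt(expect)


def test_diagnostic_sites_fully_associated_with_arrangement(default_panel):
    """Before tract implantation, arrangement determines the allele at every
    diagnostic site (pairwise R^2 = 1 among haplotypes)."""
    cfg, panel, truth = default_panel
    idx = np.searchsorted(panel.pos, truth.diagnostic_pos)
    sample_col = {s: j for j, s in enumerate(panel.samples)}
    for (sample, hap), arr in truth.arrangement.items():
        j = sample_col[sample]
        g = panel.gt[idx, j, hap]
        called = g != -1
        expected = (np.asarray(truth.diagnostic_carrier) == arr).astype(np.int8)
        assert np.array_equal(g[called], expected[called])


class TestConversionTracts:
    def _run(self, b, seed=0, tracts=120):
        cfg = SimConfig(
            seed=seed,
            conversion_tracts=tracts,
            gc_bias=b,
            conversion_recipients=("pop2_1", "pop2_2", "pop2_3"),
            missing_rate=0.0,
        )
        panel, truth = simulate_panel(cfg)
        return implant_conversion_tracts(panel, truth, cfg)

    def test_unbiased_acceptance_is_symmetric(self):
        _, truth = self._run(b=0.5)
        events = [
            o for t in truth.tracts for o in t.outcomes
            if (o[1] in "GC") != (o[2] in "GC")  # GC-changing mismatches only
        ]
        assert len(events) >= 1000
        toward_gc = sum(1 for o in events if o[1] in "GC" and o[3])
        n_gc_donor = sum(1 for o in events if o[1] in "GC")
        p = stats.binomtest(toward_gc, n_gc_donor, 0.5).pvalue
        assert p > 0.01

    def test_full_bias_boundary(self):
        _, truth = self._run(b=1.0)
        for t in truth.tracts:
            for pos, donor, rec, accepted in t.outcomes:
                if donor in "GC" and rec in "AT":
                    assert accepted
                elif donor in "AT" and rec in "GC":
                    assert not accepted

    def test_tract_lengths_within_configured_range(self):
        _, truth = self._run(b=0.68)
        lengths = [t.end - t.start for t in truth.tracts]
        assert lengths and all(50 <= ln <= 1000 for ln in lengths)
        for t in truth.tracts:
            assert t.start >= 500_000 and t.end <= 1_500_000

    def test_truth_matches_changed_loci(self):
        cfg = SimConfig(
            seed=3, conversion_tracts=20, conversion_recipients=("pop2_1",),
            missing_rate=0.0,
        )
        panel, truth = simulate_panel(cfg)
        before = panel.gt.copy()
        panel, truth = implant_conversion_tracts(panel, truth, cfg)
        changed = set(panel.pos[np.flatnonzero((panel.gt != before).any(axis=(1, 2)))])
        accepted = {o[0] for t in truth.tracts for o in t.outcomes if o[3]}
        assert changed <= accepted  # later tracts may re-touch an already-converted site


class TestDoubleCrossover:
    def _cfg(self, length=27_500, seed=0):
        return SimConfig(
            seed=seed,
            missing_rate=0.0,
            dc_tract=DcTract(recipients=("pop1_1",), start=900_000, length=length),
        )

    def test_recipient_becomes_heterozygous_inside_tract(self):
        cfg = self._cfg()
        panel, truth = simulate_panel(cfg)
        panel, truth = implant_double_crossover(panel, truth, cfg)
        j = panel.samples.index("pop1_1")
        sel = (truth.diagnostic_pos > 900_000) & (truth.diagnostic_pos <= 927_500)
        idx = np.searchsorted(panel.pos, truth.diagnostic_pos[sel])
        assert sel.sum() > 0
        g = panel.gt[idx, j]
        assert np.all(g[:, 0] != g[:, 1])

    def test_sites_outside_tract_untouched(self):
        cfg = self._cfg()
        panel, truth = simulate_panel(cfg)
        before = panel.gt.copy()
        panel, truth = implant_double_crossover(panel, truth, cfg)
        outside = (panel.pos <= 900_000) | (panel.pos > 927_500)
        assert np.array_equal(panel.gt[outside], before[outside])

    def test_zero_length_is_identity(self):
        cfg = self._cfg(length=0)
        panel, truth = simulate_panel(cfg)
        before = panel.gt.copy()
        panel, truth = implant_double_crossover(panel, truth, cfg)
        assert np.array_equal(panel.gt, before)
        assert not truth.tracts

    def test_tract_outside_inversion_rejected(self):
        cfg = SimConfig(
            seed=0,
            dc_tract=DcTract(recipients=("pop1_1",), start=1_490_000, length=50_000),
        )
        panel, truth = simulate_panel(cfg)
        with pytest.raises(ValueError, match="inside the inversion"):
            implant_double_crossover(panel, truth, cfg)


class TestContigBlocks:
    def test_colinear_and_split_contigs(self):
        cfg = SimConfig(seed=0)
        blocks, (s, e) = simulate_contig_blocks(cfg, seed=1)
        per_contig = {}
        for b in blocks:
            per_contig.setdefault(b.qname, []).append(b)
        saw_split = False
        for qname, bl in per_contig.items():
            t_lo = min(b.tstart for b in bl)
            t_hi = max(b.tend for b in bl)
            if len(bl) == 1 and (t_hi <= s or t_lo >= e):
                assert bl[0].strand == "+"
            if len(bl) == 2:
                saw_split = True
                assert {b.strand for b in bl} == {"+", "-"}
                inside = [b for b in bl if s <= b.tstart and b.tend <= e]
                outside = [b for b in bl if b.tend <= s or b.tstart >= e]
                assert len(inside) == 1 and len(outside) == 1
        assert saw_split

    def test_fixed_seed_is_deterministic(self, tmp_path):
        from supergene_kit.simdata import write_blocks_tsv

        cfg = SimConfig(seed=0)
        for k in (1, 2):
            blocks, _ = simulate_contig_blocks(cfg, seed=9)
            write_blocks_tsv(blocks, tmp_path / f"b{k}.tsv")
        assert (tmp_path / "b1.tsv").read_bytes() == (tmp_path / "b2.tsv").read_bytes()

    def test_oversized_contigs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_contig_blocks(SimConfig(seed=0), seed=0, mean_contig=5_000_000)


class TestWindowTrees:
    ORDER = ["pop1", "pop2", "pop3"]

    def test_zero_jitter_reproduces_consensus(self):
        wts = simulate_window_trees(
            self.ORDER, [1.0, 2.0], [1.0, 5.0], n_windows=2, jitter_sd=0.0,
            supergene_interval=(250_000, 500_000), n_samples=10, seed=0,
        )
        for w in wts:
            from supergene_kit.profiles import ladder_profile_from_tree

            ref = ladder_profile_from_tree(w.consensus_newick)
            for s in w.sample_newicks:
                got = ladder_profile_from_tree(s)
                assert got[0] == ref[0]
                assert np.allclose(got[1], ref[1])

    def test_supergene_windows_have_older_root(self):
        from supergene_kit.profiles import ladder_profile_from_tree

        wts = simulate_window_trees(
            self.ORDER, [1.0, 2.0], [1.0, 8.0], n_windows=4, jitter_sd=0.05,
            supergene_interval=(500_000, 1_000_000), n_samples=5, seed=1,
        )
        roots = [max(ladder_profile_from_tree(w.consensus_newick)[1]) for w in wts]
        assert roots[2] > roots[0] and roots[3] > roots[1]

    def test_fixed_seed_identical_newick(self):
        a = simulate_window_trees(self.ORDER, [1, 2], [1, 5], 2, n_samples=5, seed=7)
        b = simulate_window_trees(self.ORDER, [1, 2], [1, 5], 2, n_samples=5, seed=7)
        assert [w.sample_newicks for w in a] == [w.sample_newicks for w in b]


def test_write_outputs_roundtrip_and_truth_rows(tmp_path):
    cfg = SimConfig(
        seed=2, conversion_tracts=5, conversion_recipients=("pop2_1",),
    )
    panel, truth = simulate_panel(cfg)
    panel, truth = implant_conversion_tracts(panel, truth, cfg)
    paths = write_outputs(panel, truth, tmp_path)
    back = GenotypeMatrix.from_vcf(paths["vcf"])
    assert back.samples == panel.samples
    assert np.array_equal(back.pos, panel.pos)
    assert np.array_equal(back.gt, panel.gt)
    assert np.all(np.diff(back.pos) > 0)
    n_rows = sum(1 for _ in open(paths["truth"])) - 1
    assert n_rows == len(truth.arrangement) + len(truth.tracts)
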