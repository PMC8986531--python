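"""Parameter-recovery and calibration experiments on simulated panels.

These functions define the package's standard study conditions: repeated
simulation under a fixed configuration followed by the analysis whose
operating characteristics are being measured. They back both the test suite
and the reproduction script.

Study conditions (chosen once; see docs/methods.md):

* Null D calibration: default three-population geometry with a dense
  polymorphic background (>= 50,000 polarized sites), no gene flux.
* Gene-flux power: 150 conversion tracts per recipient haplotype into every
  haplotype of one ancestral-arrangement population, emulating a gene-flux
  signal of the magnitude reported for strong empirical cases (D ~ 0.38).
* Boundary recovery: default panel; LD profile over the filtered ingroup.
* Tract recovery: a 27.5 kb double-crossover tract carried heterozygously by
  two individuals, with within-inversion variation purely
  arrangement-diagnostic and no genotype missingness (exact-endpoint
  regime).
"""

from __future__ import annotations

import numpy as np

from .conversion_gc import classify_sites_hard, gc_bias_test
from .dstats import orient_trio, patterson_d_jackknife, polarize_sites
from .painting import detect_het_tract, informative_sites, paint_genotypes
from .popgen_stats import delimit_high_ld, dosage_r2, ld_span_sum
from .simdata import (
    DcTract,
    SimConfig,
    implant_conversion_tracts,
    implant_double_crossover,
    simulate_panel,
)
from .vcf_filters import mask_genotypes, site_filters

__all__ = [
    "null_d_calibration",
    "gene_flux_power",
    "boundary_recovery",
    "tract_recovery",
]


def _groups(cfg: SimConfig) -> dict[str, list[str]]:
    return {
        p: [f"{p}_{i}" for i in range(1, cfg.samples_per_population + 1)]
        for p in cfg.populations
    }


def null_d_calibration(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """|Z| of Patterson's D across seeds with no gene flux.

    Dense panels (>= 5e4 polarized sites) under the default geometry; the
    trio is taken in its true order (fixed topology). Returns the number of
    runs with |Z| > 3 and the smallest polarized-site count seen.
    """
    n_exceed = 0
    min_sites = np.inf
    zs = []
    for k in range(n_seeds):
        cfg = SimConfig(seed=base_seed + k, poly_density=0.03)
        panel, _ = simulate_panel(cfg)
        table = polarize_sites(panel, _groups(cfg), ["outgroup"])
        res = patterson_d_jackknife(table, ("pop1", "pop2", "pop3"))
        zs.append(res.z)
        n_exceed += abs(res.z) > 3
        min_sites = min(min_sites, len(table))
    return {
        "n_seeds": n_seeds,
        "n_exceed": int(n_exceed),
        "min_sites": int(min_sites),
        "z": zs,
    }


def _power_config(seed: int, b: float) -> SimConfig:
    return SimConfig(
        seed=seed,
        conversion_tracts=150,
        gc_bias=b,
        conversion_recipients=tuple(f"pop2_{i}" for i in range(1, 11)),
    )


def gene_flux_power(n_seeds: int = 50, b: float = 0.8, base_seed: int = 0) -> dict:
    """Joint power of D_BBAA (Z > 3) and the one-sided GC test (p < 0.05).

    Conversion tracts are copied from the derived arrangement into every
    haplotype of population pop2; the trio is (pop1, pop2, pop3-group)
    oriented by the BBAA rule. At b = 0.5 the same procedure measures the
    GC test's type-I error.
    """
    n_d = n_gc = n_both = 0
    min_converted = np.inf
    d_values: list[float] = []
    for k in range(n_seeds):
        cfg = _power_config(base_seed + k, b)
        panel, truth = simulate_panel(cfg)
        panel, truth = implant_conversion_tracts(panel, truth, cfg)
        n_conv = sum(t.n_accepted for t in truth.tracts)
        min_converted = min(min_converted, n_conv)
        table = polarize_sites(panel, _groups(cfg), ["outgroup"])
        trio = orient_trio(table, ("pop1", "pop2", "pop3"), mode="BBAA")
        res = patterson_d_jackknife(table, trio, orientation="BBAA")
        labels = classify_sites_hard(table, trio)
        gc = gc_bias_test(
            table.loc[labels == "ABBA", "gc"].to_numpy(),
            table.loc[labels == "BBAA", "gc"].to_numpy(),
        )
        d_ok = res.z > 3
        gc_ok = gc.p_one_sided < 0.05
        n_d += d_ok
        n_gc += gc_ok
        n_both += d_ok and gc_ok
        d_values.append(res.d)
    return {
        "n_seeds": n_seeds,
        "n_d": int(n_d),
        "n_gc": int(n_gc),
        "n_both": int(n_both),
        "min_converted_sites": int(min_converted),
        "mean_d": float(np.mean(d_values)),
    }


def boundary_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """High-LD interval calls vs the true inversion, in SNP positions.

    The called boundary must land within five SNP positions (on the profiled
    SNP list) of the outermost diagnostic site on each side.
    """
    n_ok = 0
    worst = 0
    for k in range(n_seeds):
        cfg = SimConfig(seed=base_seed + k)
        panel, truth = simulate_panel(cfg)
        gm = panel.take_samples([s for s in panel.samples if s != "outgroup"])
        gm = site_filters(mask_genotypes(gm), min_mac=5)
        profile = ld_span_sum(dosage_r2(gm))
        intervals = delimit_high_ld(profile)
        if not intervals:
            worst = max(worst, 10**9)
            continue
        lo, hi = max(intervals, key=lambda iv: iv[1] - iv[0])
        off_l = abs(
            np.searchsorted(profile.pos, lo)
            - np.searchsorted(profile.pos, truth.diagnostic_pos[0])
        )
        off_r = abs(
            np.searchsorted(profile.pos, hi - 1)
            - np.searchsorted(profile.pos, truth.diagnostic_pos[-1])
        )
        worst = max(worst, off_l, off_r)
        n_ok += off_l <= 5 and off_r <= 5
    return {"n_seeds": n_seeds, "n_ok": int(n_ok), "worst_offset_snps": int(worst)}


def tract_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Exact endpoint recovery of the implanted double-crossover tract.

    The detected run must span exactly the outermost informative sites
    inside the implanted interval; the focal individuals' population is in
    neither frequency group.
    """
    dc = DcTract(recipients=("pop1_1", "pop1_2"), start=950_000, length=27_500)
    n_ok = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            seed=base_seed + k, missing_rate=0.0, inside_poly_factor=0.0, dc_tract=dc,
        )
        panel, truth = simulate_panel(cfg)
        panel, truth = implant_double_crossover(panel, truth, cfg)
        der = [f"pop3_{i}" for i in range(1, 11)]
        anc = [f"pop2_{i}" for i in range(1, 11)]
        sites = informative_sites(panel, der, anc)
        pm = paint_genotypes(panel, sites, anc + der + list(dc.recipients))
        calls = detect_het_tract(pm, list(dc.recipients))
        in_tract = sites[(sites.pos > dc.start) & (sites.pos <= dc.start + dc.length)]
        n_ok += (
            len(calls) == 1
            and len(in_tract) > 0
            and calls[0].start == int(in_tract.pos.iloc[0])
            and calls[0].end == int(in_tract.pos.iloc[-1])
        )
    return {"n_seeds": n_seeds, "n_ok": int(n_ok)}
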