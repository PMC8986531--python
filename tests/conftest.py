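import numpy as np
import pytest

from supergene_kit.genotypes import GenotypeMatrix


def build_gm(records, samples=None, dp=None, gq=None):
    """Construct a GenotypeMatrix from (pos, ref, alts, genotypes) tuples.

    genotypes: list of (a, b) allele-index pairs per sample, -1 = missing.
    """
    n_samples = len(records[0][3])
    samples = samples or [f"s{i}" for i in range(n_samples)]
    pos = np.array([r[0] for r in records], dtype=np.int64)
    ref = np.array([r[1] for r in records], dtype=object)
    alt = [tuple(r[2]) for r in records]
    gt = np.array([[list(g) for g in r[3]] for r in records], dtype=np.int8)
    kw = {}
    if dp is not None:
        kw["dp"] = np.asarray(dp, dtype=np.int32)
    if gq is not None:
        kw["gq"] = np.asarray(gq, dtype=np.int32)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(["chr1"] * len(records), dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        gt=gt,
        **kw,
    )


@pytest.fixture(scope="session")
def default_panel():
    """One default simulated panel shared across read-only tests."""
    from supergene_kit.simdata import SimConfig, simulate_panel

    cfg = SimConfig(seed=11)
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture()
def pop_groups():
    return lambda cfg: {
        p: [f"{p}_{i}" for i in range(1, cfg.samples_per_population + 1)]
        for p in cfg.populations
    }
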