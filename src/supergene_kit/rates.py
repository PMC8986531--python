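"""Coalescence-time and mutation-rate arithmetic.

The mutation rate is estimated from the mean number of substitutions between
two long-separated groups of individuals: the expected coalescence time of a
cross-group pair is the group divergence time plus the expected coalescence
time within the panmictic common ancestor (generation time times the diploid
ancestral population size), and

    mu_year = S_subs / (2 * T_coal * G_callable),
    mu_gen  = mu_year * g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "expected_coalescence_time",
    "RateResult",
    "mutation_rate",
    "mean_pairwise_substitutions",
]


def expected_coalescence_time(t_div: float, g: float, n_anc: float) -> float:
    """T_coal = T_div + g * N_anc (years)."""
    if t_div < 0 or g < 0 or n_anc < 0:
        raise ValueError("inputs must be non-negative")
    return t_div + g * n_anc


@dataclass
class RateResult:
    t_coal: float  # years
    mu_year: float  # substitutions / bp / year
    mu_gen: float  # substitutions / bp / generation

    def summary(self) -> str:
        return (
            f"T_coal = {self.t_coal:,.0f} years; "
            f"mu = {self.mu_year:.3g} /bp/year = {self.mu_gen:.3g} /bp/generation"
        )


def mutation_rate(
    s_subs: float, t_coal: float, g_callable: float, g: float
) -> RateResult:
    """Per-year and per-generation mutation rate from mean substitution counts."""
    if t_coal <= 0 or g_callable <= 0:
        raise ValueError("T_coal and callable genome size must be positive")
    mu_year = s_subs / (2.0 * t_coal * g_callable)
    return RateResult(t_coal=t_coal, mu_year=mu_year, mu_gen=mu_year * g)


def mean_pairwise_substitutions(gm, groupA, groupB) -> float:
    """Mean over cross-group pairs of per-pair expected nucleotide differences.

    For two diploids the per-site difference is the probability that one
    allele drawn from each mismatches: p_i (1 - p_j) + p_j (1 - p_i) with p
    the individual alt dosage / 2. Missing genotypes are skipped pairwise.
    """
    ia = gm.sample_indices(groupA)
    ib = gm.sample_indices(groupB)
    d = gm.dosage() / 2.0  # (sites, samples), nan = missing
    total = 0.0
    n_pairs = 0
    for i in ia:
        pi = d[:, i]
        for j in ib:
            pj = d[:, j]
            ok = ~np.isnan(pi) & ~np.isnan(pj)
            total += float((pi[ok] * (1 - pj[ok]) + pj[ok] * (1 - pi[ok])).sum())
            n_pairs += 1
    return total / n_pairs
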