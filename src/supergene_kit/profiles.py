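"""Stacked divergence-time profiles from per-window tree samples.

A ladderized ultrametric population tree can be summarized losslessly by its
tip order together with the divergence times between adjacent tips: the
original tree (topology and node heights) is recovered by single-linkage
clustering of the implied pairwise divergence matrix, where
t(p_i, p_j) = max of the adjacent times between them. Stacking the adjacent
times as cumulative vertical positions per window yields the genome-wide
divergence-time profile plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "WindowTreeSet",
    "qc_window",
    "ladder_profile_from_tree",
    "stack_profiles",
    "reconstruct_tree",
    "select_window_snps",
    "divergence_matrix",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class WindowTreeSet:
    """Posterior tree sample + consensus tree for one genomic window."""

    window: tuple[int, int]
    consensus_newick: str
    sample_newicks: list[str]
    n_usable_snps: int
    min_ess: float


# ----------------------------------------------------------------------
def select_window_snps(
    gm,
    window_bp: int = 250_000,
    min_spacing_bp: int = 50,
    min_snps: int = 500,
    max_snps: int = 1000,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Per-window SNP subsets for window-tree inference.

    Greedy left-to-right thinning enforces pairwise spacing >=
    ``min_spacing_bp``; windows with fewer than ``min_snps`` surviving SNPs
    are dropped, and windows with more than ``max_snps`` are downsampled
    uniformly at random with the given seed. Returns window start ->
    site-index array.
    """
    rng = np.random.default_rng(seed)
    pos = gm.pos
    kept = []
    last = -np.inf
    for i, p in enumerate(pos):
        if p - last >= min_spacing_bp:
            kept.append(i)
            last = p
    kept = np.asarray(kept, dtype=int)
    out: dict[int, np.ndarray] = {}
    if kept.size == 0:
        return out
    starts = (pos[kept] - 1) // window_bp * window_bp
    for w0 in np.unique(starts):
        sel = kept[starts == w0]
        if sel.size < min_snps:
            continue
        if sel.size > max_snps:
            sel = np.sort(rng.choice(sel, size=max_snps, replace=False))
        out[int(w0)] = sel
    return out


def qc_window(
    wts: WindowTreeSet,
    min_snps: int = 300,
    min_ess: float = 100,
    min_mean_bpp: float = 0.5,
) -> tuple[bool, str | None]:
    """Keep/drop decision with reason; all cutoffs are strict ("below")."""
    if wts.n_usable_snps < min_snps:
        return False, f"n_usable_snps {wts.n_usable_snps} < {min_snps}"
    if wts.min_ess < min_ess:
        return False, f"min_ess {wts.min_ess:.0f} < {min_ess}"
    tree = dendropy.Tree.get(data=wts.consensus_newick, schema="newick")
    supports = []
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        if nd.label is None:
            raise ValueError(
                f"window {wts.window}: consensus tree lacks node supports"
            )
        supports.append(float(nd.label))
    if not supports:
        raise ValueError(f"window {wts.window}: consensus tree has no internal supports")
    mean_bpp = float(np.mean(supports))
    if mean_bpp < min_mean_bpp:
        return False, f"mean BPP {mean_bpp:.3f} < {min_mean_bpp}"
    return True, None


# ----------------------------------------------------------------------
def _node_heights(tree: dendropy.Tree) -> dict:
    """Node -> height above the leaves; errors if not ultrametric."""
    depth: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    leaf_depths = [depth[lf] for lf in tree.leaf_node_iter()]
    t_max = max(leaf_depths)
    if t_max > 0 and (t_max - min(leaf_depths)) / t_max > ULTRAMETRIC_RTOL:
        raise ValueError("tree is not ultrametric within tolerance")
    return {nd: t_max - d for nd, d in depth.items()}


def _ladderize(tree: dendropy.Tree) -> None:
    """Deterministic ladderization: smaller clades first, ties by smallest taxon."""
    size: dict = {}
    min_lab: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            size[nd] = 1
            min_lab[nd] = nd.taxon.label
        else:
            size[nd] = sum(size[c] for c in nd.child_nodes())
            min_lab[nd] = min(min_lab[c] for c in nd.child_nodes())
    for nd in tree.preorder_internal_node_iter():
        nd.set_child_nodes(
            sorted(nd.child_nodes(), key=lambda c: (size[c], min_lab[c]))
        )


def ladder_profile_from_tree(
    tree: dendropy.Tree | str,
    outgroups: Sequence[str] = (),
) -> tuple[list[str], list[float]]:
    """Tip order and adjacent divergence times of a ladderized ultrametric tree.

    Outgroups (if present) are pruned first; the tree is then ladderized
    deterministically and t_k is the MRCA height of adjacent tips
    (p_k, p_{k+1}).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    else:
        tree = tree.clone(depth=1)
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    to_prune = [t for t in outgroups if t in present]
    if to_prune:
        if len(present - set(to_prune)) < 1:
            raise ValueError("pruning outgroups would leave no taxa")
        tree.prune_taxa_with_labels(to_prune)
        tree.purge_taxon_namespace()
    heights = _node_heights(tree)
    _ladderize(tree)
    tips = [lf for lf in tree.leaf_node_iter()]
    order = [lf.taxon.label for lf in tips]
    t_k: list[float] = []
    for a, b in zip(tips[:-1], tips[1:]):
        mrca = _mrca_node(tree, a, b)
        t_k.append(float(heights[mrca]))
    return order, t_k


def _mrca_node(tree, a, b):
    anc_a = set()
    nd = a
    while nd is not None:
        anc_a.add(id(nd))
        nd = nd.parent_node
    nd = b
    while nd is not None:
        if id(nd) in anc_a:
            # resolve identity back to the node object
            m = b
            while m is not None:
                if id(m) == id(nd):
                    return m
                m = m.parent_node
        nd = nd.parent_node
    raise RuntimeError("no common ancestor")  # pragma: no cover


def reconstruct_tree(order: Sequence[str], t_k: Sequence[float]) -> dendropy.Tree:
    """Rebuild the ultrametric tree implied by a ladder profile.

    The implied divergence time between tips i < j is max(t_k for k in
    [i, j)); splitting recursively at the largest adjacent time is
    single-linkage clustering of that matrix and returns the tree with its
    original topology and node heights.
    """
    if len(t_k) != len(order) - 1:
        raise ValueError("need exactly len(order) - 1 adjacent times")
    if any(t < 0 for t in t_k):
        raise ValueError("divergence times must be non-negative")
    taxa = dendropy.TaxonNamespace(list(order))
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(names, times, parent_height):
        node = dendropy.Node()
        if len(names) == 1:
            node.taxon = taxa.get_taxon(names[0])
            node.edge.length = parent_height
            return node
        k = int(np.argmax(times))
        h = float(times[k])
        node.edge.length = parent_height - h
        node.add_child(build(names[: k + 1], times[:k], h))
        node.add_child(build(names[k + 1 :], times[k + 1 :], h))
        return node

    root_h = float(max(t_k)) if t_k else 0.0
    root = build(list(order), list(t_k), root_h)
    root.edge.length = None
    tree.seed_node = root
    return tree


def divergence_matrix(order: Sequence[str], t_k: Sequence[float]) -> pd.DataFrame:
    """Pairwise divergence times implied by a ladder profile."""
    n = len(order)
    m = np.zeros((n, n))
    for i in range(n):
        running = 0.0
        for j in range(i + 1, n):
            running = max(running, t_k[j - 1])
            m[i, j] = m[j, i] = running
    return pd.DataFrame(m, index=list(order), columns=list(order))


# ----------------------------------------------------------------------
def stack_profiles(
    window_profiles: dict[int, tuple[Sequence[str], Sequence[float]]],
) -> pd.DataFrame:
    """Long-format stacked positions: y_1 = 0, y_{k+1} = y_k + t_k per window."""
    taxsets = {frozenset(p[0]) for p in window_profiles.values()}
    if len(taxsets) > 1:
        raise ValueError(f"taxon sets differ across windows: {sorted(map(sorted, taxsets))}")
    rows = []
    for w, (order, t_k) in sorted(window_profiles.items()):
        y = np.concatenate([[0.0], np.cumsum(t_k)])
        for pop, yy in zip(order, y):
            rows.append((w, pop, float(yy)))
    return pd.DataFrame(rows, columns=["window", "population", "y"])


def stack_profile_samples(
    window_samples: dict[int, list[tuple[Sequence[str], Sequence[float]]]],
) -> pd.DataFrame:
    """Summary (mean and central 95% interval) of stacked positions per window.

    Each window holds profiles from a posterior tree sample; y is computed
    per tree and summarized per population.
    """
    rows = []
    for w, profiles in sorted(window_samples.items()):
        per_pop: dict[str, list[float]] = {}
        for order, t_k in profiles:
            y = np.concatenate([[0.0], np.cumsum(t_k)])
            for pop, yy in zip(order, y):
                per_pop.setdefault(pop, []).append(float(yy))
        for pop, ys in per_pop.items():
            ys = np.asarray(ys)
            rows.append(
                (w, pop, float(ys.mean()), float(np.quantile(ys, 0.025)),
                 float(np.quantile(ys, 0.975)))
            )
    return pd.DataFrame(rows, columns=["window", "population", "y", "lower", "upper"])
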