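"""Variant-profile distances, neighbor joining, bootstrap, rooting, Grafen.

Distances between samples are counts of differing chosen alleles divided by
the total number of variants detected on the genome (fixed denominator);
sites missing in either profile are excluded from the numerator only.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .strain_profiles import VariantProfile

__all__ = [
    "profile_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_with_outgroup",
    "ultrametrize_grafen",
    "compare_topologies",
    "tree_bipartitions",
    "leaf_labels",
]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def profile_distance(
    p: VariantProfile, q: VariantProfile, total_variants: int
) -> float:
    """Pairwise profile distance on a fixed total-variant denominator."""
    if total_variants <= 0:
        raise ValueError("total_variants must be positive")
    if p.n_sites != q.n_sites:
        raise ValueError("profiles do not share a site list")
    both = ~(p.missing | q.missing)
    diff = int(np.sum((p.chosen != q.chosen) & both))
    return diff / total_variants


def distance_matrix(
    profiles: Sequence[VariantProfile], total_variants: int
) -> tuple[list[str], np.ndarray]:
    labels = [p.sample for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = profile_distance(
                profiles[i], profiles[j], total_variants
            )
    return labels, d


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei agglomeration on the Q-criterion)
# ---------------------------------------------------------------------------

def neighbor_joining(labels: Sequence[str], d: np.ndarray) -> dendropy.Tree:
    """Classic NJ returning an unrooted dendropy tree.

    Ties on the Q-criterion break on the lexicographically smallest
    (label, label) pair, where an internal cluster carries the smallest tip
    label it contains. Negative inferred branch lengths are clamped to zero
    with the deficit transferred to the sister branch.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(d, dtype=float)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")

    tns = dendropy.TaxonNamespace(list(labels))
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nodes.append(dendropy.Node(taxon=tns.get_taxon(lab)))
    cluster_label = list(labels)  # min tip label per active cluster
    active = list(range(n))
    D = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        q = np.minimum(q, q.T)  # exact symmetry despite fp summation order
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] == qmin:
                    la, lb = cluster_label[active[a]], cluster_label[active[b]]
                    key = (min(la, lb), max(la, lb))
                    if best is None or key < best:
                        best, bi, bj = key, a, b
        i, j = active[bi], active[bj]
        li = sub[bi, bj] / 2 + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = sub[bi, bj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node to every other active cluster
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - D[i, j]) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        cluster_label.append(min(cluster_label[i], cluster_label[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, topology comparison
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as label sets on the side away from the
    smallest label (an orientation-free normal form)."""
    all_labels = leaf_labels(tree)
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(frozenset(side))
    return out


def compare_topologies(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[int, set[frozenset[str]], set[frozenset[str]]]:
    """Robinson–Foulds distance plus (shared, conflicting) bipartitions."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"tip sets differ: only-first={sorted(l1 - l2)}, "
            f"only-second={sorted(l2 - l1)}"
        )
    b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
    shared = b1 & b2
    conflicting = b1 ^ b2
    return len(conflicting), shared, conflicting


# ---------------------------------------------------------------------------
# Bootstrap supports
# ---------------------------------------------------------------------------

def bootstrap_support(
    profiles: Sequence[VariantProfile],
    total_variants: int,
    n_reps: int = 1000,
    seed: int | None = None,
) -> dendropy.Tree:
    """Site-resampling bootstrap: supports (%) on the main NJ tree's edges.

    Variant-site columns are resampled with replacement; the support of each
    internal bipartition of the main tree is the percentage of replicate NJ
    trees containing it, written as the internal node label.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if len(profiles) < 4:
        raise ValueError("bootstrap needs at least 4 profiles")
    rng = np.random.default_rng(seed)
    labels, d = distance_matrix(profiles, total_variants)
    main = neighbor_joining(labels, d)
    n_sites = profiles[0].n_sites
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(main)}
    for _ in range(n_reps):
        idx = rng.integers(0, n_sites, n_sites)
        resampled = [
            VariantProfile(p.sample, p.chosen[idx], p.tie[idx], p.missing[idx])
            for p in profiles
        ]
        rl, rd = distance_matrix(resampled, total_variants)
        rep_bps = tree_bipartitions(neighbor_joining(rl, rd))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_labels = leaf_labels(main)
    ref = min(all_labels)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            pct = 100.0 * counts[frozenset(side)] / n_reps
            node.label = str(int(round(pct)))
    return main


# ---------------------------------------------------------------------------
# Rooting and ultrametrization
# ---------------------------------------------------------------------------

def root_with_outgroup(
    tree: dendropy.Tree, outgroup: Sequence[str]
) -> dendropy.Tree:
    """Root on the branch separating the outgroup, splitting its length.

    The outgroup must form one side of an edge of the unrooted tree
    (clade-compatible); otherwise the conflicting tips are reported.
    """
    og = set(outgroup)
    tips = leaf_labels(tree)
    if not og:
        raise ValueError("empty outgroup")
    unknown = og - tips
    if unknown:
        raise ValueError(f"outgroup tips not in tree: {sorted(unknown)}")
    if og == tips:
        raise ValueError("outgroup cannot contain every tip")
    t = tree.clone(depth=1)
    target = None
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if side == og or side == tips - og:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic in the tree"
        )
    edge = target.edge
    length = edge.length if edge.length is not None else 0.0
    t.reroot_at_edge(edge, update_bipartitions=False)
    # reroot_at_edge leaves length placement implementation-defined; enforce
    # an even split of the original branch across the two root children.
    root = t.seed_node
    children = root.child_nodes()
    if len(children) == 2:
        for ch in children:
            ch.edge.length = length / 2
    t.is_rooted = True
    return t


def ultrametrize_grafen(tree: dendropy.Tree) -> dendropy.Tree:
    """Grafen's method: node height = (clade tip count - 1) / (n tips - 1).

    Branch length becomes parent height minus child height, so every
    root-to-tip path has length 1 (0 for a single-tip tree).
    """
    t = tree.clone(depth=1)
    n_tips = sum(1 for _ in t.leaf_node_iter())
    denom = max(n_tips - 1, 1)
    heights: dict[dendropy.Node, float] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            k = sum(1 for _ in node.leaf_iter())
            heights[node] = (k - 1) / denom
    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    t.is_rooted = True
    return t
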