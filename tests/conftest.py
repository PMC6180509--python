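"""Shared helpers: tiny matrix builders and random tree generators."""

from __future__ import annotations

import numpy as np
import dendropy
import pytest

from holostrain.model import AlleleCountMatrix, Site


def make_matrix(site_specs, samples, depths, missing=None):
    """Build an AlleleCountMatrix from compact literals.

    site_specs: list of (replicon, pos, ref, alts-tuple)
    depths: list (per site) of list (per sample) of per-allele counts
    """
    sites = [Site(r, p, ref, tuple(alts)) for r, p, ref, alts in site_specs]
    d = [np.array(x, dtype=np.int64) for x in depths]
    m = [np.array(x, dtype=bool) for x in missing] if missing else None
    return AlleleCountMatrix(sites, samples, d, m)


def random_binary_tree(labels, rng, min_len=0.1, max_len=1.0):
    """Random rooted binary tree over the given labels with random lengths."""
    tns = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(min_len, max_len))
        b.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def patristic_matrix(tree, labels):
    """Pairwise path-length matrix in the order of ``labels`` (via dendropy)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
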