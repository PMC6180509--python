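import dendropy
import numpy as np
import pytest

from holostrain.io_formats import tree_from_newick, tree_to_newick
from holostrain.profile_phylogeny import (
    bootstrap_support,
    compare_topologies,
    distance_matrix,
    neighbor_joining,
    profile_distance,
    root_with_outgroup,
    tree_bipartitions,
    ultrametrize_grafen,
)
from holostrain.strain_profiles import VariantProfile

from conftest import patristic_matrix, random_binary_tree


def mk_profile(sample, chosen, missing=None):
    n = len(chosen)
    return VariantProfile(
        sample,
        np.array(chosen),
        np.zeros(n, dtype=bool),
        np.array(missing if missing is not None else [False] * n),
    )


# ---------------------------------------------------------------------------
# profile_distance
# ---------------------------------------------------------------------------

def test_distance_identical_zero():
    p = mk_profile("a", [0, 1, 1, 0])
    q = mk_profile("b", [0, 1, 1, 0])
    assert profile_distance(p, q, 50) == 0.0


def test_distance_3_of_10():
    p = mk_profile("a", [0] * 10)
    q = mk_profile("b", [1, 1, 1] + [0] * 7)
    assert profile_distance(p, q, 10) == 0.3


def test_distance_all_different():
    p = mk_profile("a", [0] * 10)
    q = mk_profile("b", [1] * 10)
    assert profile_distance(p, q, 10) == 1.0


def test_distance_missing_excluded_from_numerator():
    p = mk_profile("a", [0, 0], missing=[True, False])
    q = mk_profile("b", [1, 1])
    assert profile_distance(p, q, 2) == 0.5


def test_distance_zero_total_errors():
    p = mk_profile("a", [0])
    with pytest.raises(ValueError):
        profile_distance(p, p, 0)


def test_distance_semimetric_properties(rng):
    ps = [
        mk_profile(f"s{i}", rng.integers(0, 3, 30), missing=rng.random(30) < 0.1)
        for i in range(8)
    ]
    labels, d = distance_matrix(ps, 30)
    assert np.allclose(d, d.T, atol=1e-12)
    assert np.all(np.diag(d) == 0)
    assert d.min() >= 0 and d.max() <= 1


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    t = neighbor_joining(["A", "B", "C"], d)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_too_few_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(["A", "B"], np.zeros((2, 2)))


def test_nj_nan_errors():
    d = np.full((3, 3), np.nan)
    with pytest.raises(ValueError, match="NaN"):
        neighbor_joining(["A", "B", "C"], d)


def test_nj_recovers_additive_8_taxa(rng):
    # DERIVED: generator oracle — patristic distances of a known tree
    labels = [f"t{i}" for i in range(8)]
    true = random_binary_tree(labels, rng)
    d = patristic_matrix(true, labels)
    nj = neighbor_joining(labels, d)
    rf, _, _ = compare_topologies(true, nj)
    assert rf == 0
    assert np.allclose(patristic_matrix(nj, labels), d, atol=1e-9)


def test_nj_all_equal_deterministic():
    d = np.ones((5, 5)) - np.eye(5)
    labels = list("ABCDE")
    t1 = neighbor_joining(labels, d)
    t2 = neighbor_joining(labels, d)
    assert tree_to_newick(t1) == tree_to_newick(t2)
    internal = [
        e.length
        for e in t1.preorder_edge_iter()
        if e.head_node is not None and not e.head_node.is_leaf()
        and e.length is not None
    ]
    assert all(abs(x) < 1e-12 for x in internal)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _congruent_profiles():
    # four non-conflicting site classes supporting ((a,b),(c,d),e):
    # 10 sites mark {a,b}, 10 mark {c,d}, 10 mark a alone, 10 mark c alone
    def row(*classes):
        out = []
        for cls in ("ab", "cd", "a", "c"):
            out += [1 if cls in classes else 0] * 10
        return out

    rows = {
        "a": row("ab", "a"),
        "b": row("ab"),
        "c": row("cd", "c"),
        "d": row("cd"),
        "e": row(),
    }
    return [mk_profile(s, v) for s, v in rows.items()]


def test_bootstrap_congruent_full_support():
    t = bootstrap_support(_congruent_profiles(), 40, n_reps=50, seed=5)
    supports = [
        int(nd.label)
        for nd in t.preorder_node_iter()
        if nd.label is not None and not nd.is_leaf()
    ]
    assert supports and all(s == 100 for s in supports)


def test_bootstrap_deterministic():
    t1 = bootstrap_support(_congruent_profiles(), 40, n_reps=25, seed=42)
    t2 = bootstrap_support(_congruent_profiles(), 40, n_reps=25, seed=42)
    assert tree_to_newick(t1) == tree_to_newick(t2)


def test_bootstrap_conflicting_site_classes(rng):
    # DERIVED: 70/30 conflicting signal on 4 taxa -> dominant bipartition
    # support lands in [70-ish, 100], checked against small-replicate runs
    n = 100
    ab = [0] * 70 + [1] * 30
    cd = [1] * 70 + [1] * 30
    prof = [
        mk_profile("a", [0] * n),
        mk_profile("b", ab),
        mk_profile("c", cd),
        mk_profile("d", [1] * 70 + [0] * 30),
    ]
    t = bootstrap_support(prof, n, n_reps=50, seed=1)
    supports = [
        int(nd.label)
        for nd in t.preorder_node_iter()
        if nd.label is not None and not nd.is_leaf()
    ]
    assert supports and 60 <= supports[0] <= 100


def test_bootstrap_nreps_validation():
    with pytest.raises(ValueError):
        bootstrap_support(_congruent_profiles(), 40, n_reps=0)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def test_root_simple_outgroup():
    t = tree_from_newick("((A:1,B:1):1,(C:1,D:3):1);")
    r = root_with_outgroup(t, ["D"])
    root_children = r.seed_node.child_nodes()
    assert len(root_children) == 2
    sides = [
        {leaf.taxon.label for leaf in ch.leaf_iter()} for ch in root_children
    ]
    assert {"D"} in sides
    # branch split equally
    assert all(ch.edge.length == pytest.approx(1.5) for ch in root_children)


def test_root_all_tips_errors():
    t = tree_from_newick("((A:1,B:1):1,C:1);")
    with pytest.raises(ValueError, match="every tip"):
        root_with_outgroup(t, ["A", "B", "C"])


def test_root_non_monophyletic_errors():
    t = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(ValueError, match="monophyletic"):
        root_with_outgroup(t, ["A", "C"])


def test_root_unroot_roundtrip(rng):
    # DERIVED: unrooting the rooted result returns the original topology
    for k in range(5):
        labels = [f"t{i}" for i in range(6 + k)]
        t = random_binary_tree(labels, rng)
        t.is_rooted = False
        r = root_with_outgroup(t, [labels[0]])
        rf, _, _ = compare_topologies(t, r)
        assert rf == 0


# ---------------------------------------------------------------------------
# Grafen ultrametrization
# ---------------------------------------------------------------------------

def test_grafen_cherry():
    t = tree_from_newick("(A:5,B:1);")
    t.is_rooted = True
    u = ultrametrize_grafen(t)
    for leaf in u.leaf_node_iter():
        assert leaf.edge.length == pytest.approx(1.0)


def test_grafen_caterpillar_heights():
    # DERIVED by hand from height = (k-1)/(n-1): root 1, then 2/3, 1/3, 0
    t = tree_from_newick("(((A:1,B:1):1,C:1):1,D:1);")
    t.is_rooted = True
    u = ultrametrize_grafen(t)
    by_label = {}
    for nd in u.preorder_node_iter():
        tips = frozenset(leaf.taxon.label for leaf in nd.leaf_iter())
        by_label[tips] = nd
    ab = by_label[frozenset({"A", "B"})]
    abc = by_label[frozenset({"A", "B", "C"})]
    assert abc.edge.length == pytest.approx(1 - 2 / 3)
    assert ab.edge.length == pytest.approx(2 / 3 - 1 / 3)
    # leaf A edge: 1/3 - 0
    a = [leaf for leaf in u.leaf_node_iter() if leaf.taxon.label == "A"][0]
    assert a.edge.length == pytest.approx(1 / 3)


def test_grafen_ultrametric_random(rng):
    for k in range(10):
        labels = [f"t{i}" for i in range(4 + k)]
        t = random_binary_tree(labels, rng)
        u = ultrametrize_grafen(t)
        depths = []
        for leaf in u.leaf_node_iter():
            d = 0.0
            nd = leaf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9
        assert depths[0] == pytest.approx(1.0)


def test_grafen_single_tip():
    t = tree_from_newick("(A:1);")
    t.is_rooted = True
    u = ultrametrize_grafen(t)  # no error; height 0 tree
    assert sum(1 for _ in u.leaf_node_iter()) == 1


# ---------------------------------------------------------------------------
# topology comparison
# ---------------------------------------------------------------------------

def test_rf_identical_zero(rng):
    labels = [f"t{i}" for i in range(7)]
    t = random_binary_tree(labels, rng)
    rf, shared, conflicting = compare_topologies(t, t)
    assert rf == 0 and not conflicting


def test_rf_four_taxon_alternatives():
    t1 = tree_from_newick("((A,B),(C,D));")
    t2 = tree_from_newick("((A,C),(B,D));")
    rf, _, _ = compare_topologies(t1, t2)
    assert rf == 2


def test_rf_tipset_mismatch():
    t1 = tree_from_newick("((A,B),(C,D));")
    t2 = tree_from_newick("((A,B),(C,E));")
    with pytest.raises(ValueError, match="only-first"):
        compare_topologies(t1, t2)


def test_rf_matches_dendropy_oracle(rng):
    # DERIVED: dendropy's bipartition machinery as the independent route
    import dendropy.calculate.treecompare as tc

    for k in range(10):
        labels = [f"t{i}" for i in range(6 + (k % 4))]
        t1 = random_binary_tree(labels, rng)
        t2 = random_binary_tree(labels, rng)
        rf, _, _ = compare_topologies(t1, t2)
        tns = dendropy.TaxonNamespace(labels)
        d1 = dendropy.Tree.get(
            data=tree_to_newick(t1), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        d2 = dendropy.Tree.get(
            data=tree_to_newick(t2), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = tc.symmetric_difference(d1, d2, is_bipartitions_updated=True)
        assert rf == expected
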