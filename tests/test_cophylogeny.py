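import numpy as np
import pytest

from holostrain.cophylogeny import (
    CostScheme,
    cospeciation_test,
    prune_unusable_tips,
    reconcile,
)
from holostrain.coverage_screen import PresenceStatus
from holostrain.io_formats import tree_from_newick

from conftest import random_binary_tree


def rooted(newick):
    t = tree_from_newick(newick)
    t.is_rooted = True
    return t


# ---------------------------------------------------------------------------
# Independent brute-force oracle: direct enumeration over per-node host
# placements with naive ancestry/path tables (no in/out recurrences).
# ---------------------------------------------------------------------------

def oracle_min_cost(host, symb, phi, costs):
    hnodes = list(host.postorder_node_iter())
    parent = {id(n): n.parent_node for n in hnodes}

    def ancestors_or_self(n):
        out = []
        while n is not None:
            out.append(id(n))
            n = parent[id(n)]
        return out

    anc = {id(n): set(ancestors_or_self(n)) for n in hnodes}

    def edge_dist(a, d):
        """Edges from host node a down to descendant d; None if not below."""
        if id(a) not in anc[id(d)]:
            return None
        steps, n = 0, d
        while n is not a:
            n = parent[id(n)]
            steps += 1
        return steps

    host_tips = {n.taxon.label: n for n in hnodes if n.is_leaf()}

    def table(p):
        """dict host-node-id -> min cost of mapping symbiont node p there."""
        if p.is_leaf():
            return {id(host_tips[phi[p.taxon.label]]): 0.0}
        c1, c2 = p.child_nodes()
        t1, t2 = table(c1), table(c2)
        by_id = {id(n): n for n in hnodes}
        out = {}
        for h in hnodes:
            best = np.inf
            hc = h.child_nodes()
            for i1, v1 in t1.items():
                for i2, v2 in t2.items():
                    h1, h2 = by_id[i1], by_id[i2]
                    d1, d2 = edge_dist(h, h1), edge_dist(h, h2)
                    # duplication: both children at or below h
                    if d1 is not None and d2 is not None:
                        best = min(
                            best,
                            costs.duplication + v1 + v2
                            + costs.loss * (d1 + d2),
                        )
                    # cospeciation: children in different child subtrees
                    if hc:
                        for l, r in ((hc[0], hc[1]), (hc[1], hc[0])):
                            dl, dr = edge_dist(l, h1), edge_dist(r, h2)
                            if dl is not None and dr is not None:
                                best = min(
                                    best,
                                    costs.cospeciation + v1 + v2
                                    + costs.loss * (dl + dr),
                                )
                    # host switch: one child below h, the other incomparable
                    inc1 = id(h) not in anc[i1] and i1 not in anc[id(h)]
                    inc2 = id(h) not in anc[i2] and i2 not in anc[id(h)]
                    if d1 is not None and inc2:
                        best = min(
                            best,
                            costs.host_switch + v1 + v2 + costs.loss * d1,
                        )
                    if d2 is not None and inc1:
                        best = min(
                            best,
                            costs.host_switch + v1 + v2 + costs.loss * d2,
                        )
            if np.isfinite(best):
                out[id(h)] = best
        return out

    return min(table(symb.seed_node).values())


# ---------------------------------------------------------------------------
# reconcile
# ---------------------------------------------------------------------------

def test_congruent_four_tips_cost_zero():
    host = rooted("((A,B),(C,D));")
    symb = rooted("((a,b),(c,d));")
    phi = {"a": "A", "b": "B", "c": "C", "d": "D"}
    r = reconcile(host, symb, phi)
    assert r.cost == 0
    assert r.n_cospeciation == 3
    assert r.n_duplication == r.n_host_switch == r.n_loss == 0


def test_single_tip_symbiont():
    host = rooted("((A,B),(C,D));")
    symb = rooted("(a);")
    r = reconcile(host, symb, {"a": "A"})
    assert r.cost == 0
    assert sum(r.event_counts.values()) == 0


def test_switch_beats_two_losses():
    # one switch (cost 1) beats cospeciation at the root plus 2 losses
    host = rooted("((A,B),(C,D));")
    symb = rooted("(a,c);")
    phi = {"a": "A", "c": "C"}
    r = reconcile(host, symb, phi)
    assert r.cost == 1
    assert r.n_host_switch == 1
    assert oracle_min_cost(host, symb, phi, CostScheme()) == 1


def test_losses_when_clade_uninfected():
    host = rooted("((A,B),(C,D));")
    symb = rooted("(a,b);")
    r = reconcile(host, symb, {"a": "A", "b": "B"})
    # cospeciation in the (A,B) clade only, no events charged above the root
    assert r.cost == 0
    assert r.n_cospeciation == 1


def test_nonbinary_errors():
    host = rooted("(A,B,C);")
    symb = rooted("(a,b);")
    with pytest.raises(ValueError, match="binary"):
        reconcile(host, symb, {"a": "A", "b": "B"})


def test_unknown_tip_errors():
    host = rooted("(A,B);")
    symb = rooted("(a,b);")
    with pytest.raises(KeyError):
        reconcile(host, symb, {"a": "A", "b": "Z"})


def test_cost_equals_event_sum(rng):
    for k in range(20):
        nh = int(rng.integers(3, 7))
        ns = int(rng.integers(2, 7))
        host = random_binary_tree([f"H{i}" for i in range(nh)], rng)
        symb = random_binary_tree([f"s{i}" for i in range(ns)], rng)
        phi = {
            f"s{i}": f"H{int(rng.integers(nh))}" for i in range(ns)
        }
        r = reconcile(host, symb, phi)
        c = CostScheme()
        assert r.cost == pytest.approx(
            r.n_cospeciation * c.cospeciation
            + r.n_duplication * c.duplication
            + r.n_host_switch * c.host_switch
            + r.n_loss * c.loss
        )


def test_dp_matches_oracle_random(rng):
    # DERIVED: exhaustive-enumeration oracle on trees with <= 6 tips
    for k in range(40):
        nh = int(rng.integers(2, 7))
        ns = int(rng.integers(2, 7))
        host = random_binary_tree([f"H{i}" for i in range(nh)], rng)
        symb = random_binary_tree([f"s{i}" for i in range(ns)], rng)
        phi = {f"s{i}": f"H{int(rng.integers(nh))}" for i in range(ns)}
        costs = CostScheme(
            cospeciation=float(rng.integers(0, 2)),
            duplication=float(rng.integers(1, 4)),
            host_switch=float(rng.integers(1, 4)),
            loss=float(rng.integers(1, 3)),
        )
        expected = oracle_min_cost(host, symb, phi, costs)
        got = reconcile(host, symb, phi, costs).cost
        assert got == pytest.approx(expected), (k, nh, ns, phi)


def test_cost_monotone_in_unit_costs(rng):
    host = random_binary_tree([f"H{i}" for i in range(5)], rng)
    symb = random_binary_tree([f"s{i}" for i in range(5)], rng)
    phi = {f"s{i}": f"H{(i * 2) % 5}" for i in range(5)}
    base = reconcile(host, symb, phi, CostScheme()).cost
    for bumped in (
        CostScheme(cospeciation=1),
        CostScheme(duplication=2),
        CostScheme(host_switch=2),
        CostScheme(loss=2),
    ):
        assert reconcile(host, symb, phi, bumped).cost >= base


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_congruent_8_tips_significant():
    labels = [f"H{i}" for i in range(8)]
    host = random_binary_tree(labels, np.random.default_rng(3))
    symb = host.clone(depth=1)
    phi = {lab: lab for lab in labels}
    res = cospeciation_test(host, symb, phi, n_perm=199, seed=11)
    assert res.cost == 0
    assert res.p_value <= 0.05


def test_permutation_deterministic():
    labels = [f"H{i}" for i in range(6)]
    host = random_binary_tree(labels, np.random.default_rng(4))
    symb = random_binary_tree(labels, np.random.default_rng(5))
    phi = {lab: lab for lab in labels}
    r1 = cospeciation_test(host, symb, phi, n_perm=99, seed=7)
    r2 = cospeciation_test(host, symb, phi, n_perm=99, seed=7)
    assert r1.p_value == r2.p_value
    assert np.array_equal(r1.permuted_costs, r2.permuted_costs)


def test_nperm_validation():
    host = rooted("(A,B);")
    with pytest.raises(ValueError):
        cospeciation_test(host, host.clone(depth=1), {"A": "A", "B": "B"}, n_perm=0)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_prune_present_low_tip():
    host = rooted("((A,B),(C,D));")
    symb = rooted("((a,b),(c,d));")
    phi = {"a": "A", "b": "B", "c": "C", "d": "D"}
    calls = {
        "a": PresenceStatus.ANALYSABLE,
        "b": PresenceStatus.PRESENT_LOW,
        "c": PresenceStatus.ANALYSABLE,
        "d": PresenceStatus.ANALYSABLE,
    }
    h2, s2, phi2 = prune_unusable_tips(host, symb, phi, calls)
    tips = {leaf.taxon.label for leaf in s2.leaf_node_iter()}
    assert tips == {"a", "c", "d"}
    assert "b" not in phi2
    # host keeps all tips (absences stay absences)
    assert len({leaf.taxon.label for leaf in h2.leaf_node_iter()}) == 4


def test_prune_noop_when_all_analysable():
    host = rooted("((A,B),(C,D));")
    symb = rooted("((a,b),(c,d));")
    phi = {"a": "A", "b": "B", "c": "C", "d": "D"}
    calls = {k: PresenceStatus.ANALYSABLE for k in phi}
    _, s2, phi2 = prune_unusable_tips(host, symb, phi, calls)
    assert {leaf.taxon.label for leaf in s2.leaf_node_iter()} == set(phi)
    assert phi2 == phi


def test_prune_preserves_path_lengths(rng):
    # DERIVED: pairwise path lengths among survivors are unchanged
    from conftest import patristic_matrix

    labels = [f"s{i}" for i in range(6)]
    symb = random_binary_tree(labels, rng)
    host = random_binary_tree([f"H{i}" for i in range(6)], rng)
    phi = {f"s{i}": f"H{i}" for i in range(6)}
    calls = {lab: PresenceStatus.ANALYSABLE for lab in labels}
    calls["s1"] = PresenceStatus.PRESENT_LOW
    before = patristic_matrix(symb, [l for l in labels if l != "s1"])
    _, s2, _ = prune_unusable_tips(host, symb, phi, calls)
    after = patristic_matrix(s2, [l for l in labels if l != "s1"])
    assert np.allclose(before, after, atol=1e-12)


def test_prune_everything_errors():
    host = rooted("(A,B);")
    symb = rooted("(a,b);")
    phi = {"a": "A", "b": "B"}
    calls = {k: PresenceStatus.PRESENT_LOW for k in phi}
    with pytest.raises(ValueError, match="every symbiont tip"):
        prune_unusable_tips(host, symb, phi, calls)
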