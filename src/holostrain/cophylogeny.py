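"""Event-cost reconciliation of a symbiont tree onto a host tree.

An exact duplication–transfer–loss dynamic program (in/out recurrences over
symbiont nodes x host nodes) replaces heuristic search: cospeciation,
duplication, host switch and loss each carry a configurable non-negative
unit cost, transfers land on host nodes not ancestrally related to the
donor, and no transfer time-consistency is enforced. Significance of the
cospeciation signal comes from permuting the tip-mapping images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .coverage_screen import PresenceCall, PresenceStatus

__all__ = [
    "CostScheme",
    "ReconciliationResult",
    "prune_unusable_tips",
    "reconcile",
    "cospeciation_test",
]

INF = float("inf")


@dataclass(frozen=True)
class CostScheme:
    cospeciation: float = 0.0
    duplication: float = 1.0
    host_switch: float = 1.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cospeciation", "duplication", "host_switch", "loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cost must be >= 0")


@dataclass
class ReconciliationResult:
    cost: float
    n_cospeciation: int
    n_duplication: int
    n_host_switch: int
    n_loss: int
    node_mapping: dict[str, str] = field(default_factory=dict)
    p_value: float | None = None
    permuted_costs: np.ndarray | None = field(default=None, repr=False)

    @property
    def event_counts(self) -> dict[str, int]:
        return {
            "cospeciation": self.n_cospeciation,
            "duplication": self.n_duplication,
            "host_switch": self.n_host_switch,
            "loss": self.n_loss,
        }


# ---------------------------------------------------------------------------
# Tree indexing
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-indexed arrays over a rooted binary tree."""

    def __init__(self, tree: dendropy.Tree, name: str) -> None:
        if any(len(nd.child_nodes()) == 1 for nd in tree.postorder_node_iter()):
            tree = tree.clone(depth=1)
            tree.suppress_unifurcations()
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self.node_of: list[dendropy.Node] = nodes
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[tuple[int, ...]] = []
        self.labels: list[str | None] = []
        for nd in nodes:
            ch = nd.child_nodes()
            if ch and len(ch) != 2:
                raise ValueError(
                    f"{name} tree is not binary at a node with {len(ch)} children"
                )
            self.children.append(tuple(self.index[id(c)] for c in ch))
            self.labels.append(nd.taxon.label if nd.taxon else nd.label)
        self.root = self.index[id(tree.seed_node)]
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        # descendant-or-self boolean matrix and edge distances
        self.desc = np.zeros((self.n, self.n), dtype=bool)
        self.edge_dist = np.full((self.n, self.n), -1, dtype=np.int64)
        for i in range(self.n):  # postorder: children before parents
            self.desc[i, i] = True
            self.edge_dist[i, i] = 0
            for c in self.children[i]:
                below = self.desc[c]
                self.desc[i] |= below
                self.edge_dist[i, below] = self.edge_dist[c, below] + 1
        comparable = self.desc | self.desc.T
        self.incomparable = ~comparable
        self.leaf_index = {
            self.labels[i]: i for i in range(self.n) if self.is_leaf[i]
        }


# ---------------------------------------------------------------------------
# Core DP
# ---------------------------------------------------------------------------

def _dp_tables(
    H: _TreeIndex, S: _TreeIndex, tip_to_host: np.ndarray, costs: CostScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal-cost tables C[p, h] and IN[p, h] over all placements."""
    nH, nS = H.n, S.n
    C = np.full((nS, nH), INF)
    IN = np.full((nS, nH), INF)
    for p in range(nS):
        if S.is_leaf[p]:
            C[p, tip_to_host[p]] = 0.0
        else:
            p1, p2 = S.children[p]
            in1, in2 = IN[p1], IN[p2]
            out1 = np.where(H.incomparable, C[p1][None, :], INF).min(axis=1)
            out2 = np.where(H.incomparable, C[p2][None, :], INF).min(axis=1)
            for h in range(nH):
                best = costs.duplication + in1[h] + in2[h]
                if not H.is_leaf[h]:
                    l, r = H.children[h]
                    spec = costs.cospeciation + min(
                        in1[l] + in2[r], in1[r] + in2[l]
                    )
                    if spec < best:
                        best = spec
                sw = costs.host_switch + min(
                    in1[h] + out2[h], in2[h] + out1[h]
                )
                if sw < best:
                    best = sw
                C[p, h] = best
        # IN[p, h]: cheapest placement of p at or below h, losses charged
        for h in range(nH):  # postorder guarantees children first
            v = C[p, h]
            for c in H.children[h]:
                v = min(v, IN[p, c] + costs.loss)
            IN[p, h] = v
    return C, IN


def _backtrack(
    H: _TreeIndex,
    S: _TreeIndex,
    tip_to_host: np.ndarray,
    costs: CostScheme,
    C: np.ndarray,
    IN: np.ndarray,
) -> tuple[dict[str, int], dict[int, int]]:
    """Recover one optimal event history.

    Ties break by event priority (cospeciation, then switch, then
    duplication; loss chains are preferred implicitly by resolving IN to the
    shallowest optimal host), then by host-node index.
    """
    counts = {"cospeciation": 0, "duplication": 0, "host_switch": 0, "loss": 0}
    mapping: dict[int, int] = {}
    eps = 1e-9

    def resolve_in(p: int, h: int) -> int:
        # walk down the host tree along the optimal loss chain
        while True:
            if C[p, h] <= IN[p, h] + eps:
                return h
            nxt = None
            for c in sorted(H.children[h]):
                if IN[p, c] + costs.loss <= IN[p, h] + eps:
                    nxt = c
                    break
            assert nxt is not None
            counts["loss"] += 1
            h = nxt

    def place(p: int, h: int) -> None:
        mapping[p] = h
        if S.is_leaf[p]:
            return
        p1, p2 = S.children[p]
        target = C[p, h]
        # cospeciation
        if not H.is_leaf[h]:
            l, r = H.children[h]
            for hl, hr in ((l, r), (r, l)):
                if costs.cospeciation + IN[p1, hl] + IN[p2, hr] <= target + eps:
                    counts["cospeciation"] += 1
                    place(p1, resolve_in(p1, hl))
                    place(p2, resolve_in(p2, hr))
                    return
        # host switch
        for stay, move in ((p1, p2), (p2, p1)):
            inc = np.flatnonzero(H.incomparable[h])
            if len(inc):
                land_costs = C[move, inc]
                best = land_costs.min()
                if costs.host_switch + IN[stay, h] + best <= target + eps:
                    counts["host_switch"] += 1
                    land = int(inc[np.argmin(land_costs)])
                    place(stay, resolve_in(stay, h))
                    place(move, land)
                    return
        # duplication
        assert costs.duplication + IN[p1, h] + IN[p2, h] <= target + eps
        counts["duplication"] += 1
        place(p1, resolve_in(p1, h))
        place(p2, resolve_in(p2, h))

    root_costs = C[S.root]
    h0 = int(np.argmin(root_costs))
    place(S.root, h0)
    return counts, mapping


def reconcile(
    host: dendropy.Tree,
    symbiont: dendropy.Tree,
    phi: Mapping[str, str],
    costs: CostScheme = CostScheme(),
) -> ReconciliationResult:
    """Minimal-cost reconciliation of a symbiont tree onto a host tree.

    ``phi`` maps every symbiont tip label to a host tip label (many-to-one
    allowed). Both trees must be rooted and binary; branch lengths are
    ignored.
    """
    H = _TreeIndex(host, "host")
    S = _TreeIndex(symbiont, "symbiont")
    tip_to_host = _map_tips(H, S, phi)
    C, IN = _dp_tables(H, S, tip_to_host, costs)
    cost = float(C[S.root].min())
    counts, mapping = _backtrack(H, S, tip_to_host, costs, C, IN)
    total = (
        counts["cospeciation"] * costs.cospeciation
        + counts["duplication"] * costs.duplication
        + counts["host_switch"] * costs.host_switch
        + counts["loss"] * costs.loss
    )
    assert abs(total - cost) < 1e-6, "event counts inconsistent with DP cost"
    named = {
        str(S.labels[p] or f"node{p}"): str(H.labels[h] or f"node{h}")
        for p, h in mapping.items()
    }
    return ReconciliationResult(
        cost=cost,
        n_cospeciation=counts["cospeciation"],
        n_duplication=counts["duplication"],
        n_host_switch=counts["host_switch"],
        n_loss=counts["loss"],
        node_mapping=named,
    )


def _map_tips(H: _TreeIndex, S: _TreeIndex, phi: Mapping[str, str]) -> np.ndarray:
    tip_to_host = np.full(S.n, -1, dtype=np.int64)
    for label, i in S.leaf_index.items():
        if label not in phi:
            raise KeyError(f"symbiont tip {label!r} missing from tip mapping")
        target = phi[label]
        if target not in H.leaf_index:
            raise KeyError(f"tip mapping image {target!r} is not a host tip")
        tip_to_host[i] = H.leaf_index[target]
    return tip_to_host


def cospeciation_test(
    host: dendropy.Tree,
    symbiont: dendropy.Tree,
    phi: Mapping[str, str],
    costs: CostScheme = CostScheme(),
    n_perm: int = 500,
    seed: int | None = None,
) -> ReconciliationResult:
    """Permutation test: is the observed cost lower than random mappings?

    The images of the tip mapping are shuffled uniformly ``n_perm`` times;
    p = (1 + #{permuted cost <= observed}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    result = reconcile(host, symbiont, phi, costs)
    H = _TreeIndex(host, "host")
    S = _TreeIndex(symbiont, "symbiont")
    base = _map_tips(H, S, phi)
    leaf_pos = np.flatnonzero(S.is_leaf)
    images = base[leaf_pos]
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(images)
        t2h = base.copy()
        t2h[leaf_pos] = shuffled
        C, _ = _dp_tables(H, S, t2h, costs)
        permuted[k] = C[S.root].min()
    result.permuted_costs = permuted
    result.p_value = float(
        (1 + int((permuted <= result.cost + 1e-12).sum())) / (n_perm + 1)
    )
    return result


def prune_unusable_tips(
    host: dendropy.Tree,
    symbiont: dendropy.Tree,
    phi: Mapping[str, str],
    calls: Sequence[PresenceCall] | Mapping[str, PresenceStatus],
) -> tuple[dendropy.Tree, dendropy.Tree, dict[str, str]]:
    """Drop symbiont tips with 1x-10x coverage (status present_low).

    Such samples carry the symbiont but too thinly for reliable variant
    calling; removing them (rather than treating them as absences) avoids
    inflating loss counts. Truly absent samples stay in the host tree.
    Unifurcations left by pruning are suppressed with branch lengths summed.
    """
    if isinstance(calls, Mapping):
        status = dict(calls)
    else:
        status = {c.sample: c.status for c in calls}
    drop = {
        leaf.taxon.label
        for leaf in symbiont.leaf_node_iter()
        if status.get(leaf.taxon.label) == PresenceStatus.PRESENT_LOW
    }
    pruned = symbiont.clone(depth=1)
    if drop:
        survivors = [
            t for t in pruned.taxon_namespace
            if t.label not in drop and any(
                leaf.taxon is t for leaf in pruned.leaf_node_iter()
            )
        ]
        if not survivors:
            raise ValueError("pruning removed every symbiont tip")
        pruned.retain_taxa(survivors)
        pruned.purge_taxon_namespace()
    new_phi = {
        k: v for k, v in phi.items() if k not in drop
    }
    return host, pruned, new_phi
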