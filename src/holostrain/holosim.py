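"""Synthetic holobiont generator with ground truth for every pipeline stage.

A Yule host tree is decorated with a symbiont history of cospeciations,
host switches and losses; strain genomes then diverge by Jukes–Cantor
substitutions (plus a small fraction of 1–3 bp indels), and per-sample
allele counts are drawn with Poisson depths and a uniform miscall model.
Error-driven candidate sites are emitted when a sample accumulates three or
more reads of the same spurious allele (a caller-evidence proxy), so the
rare-allele filter has realistic false positives to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .model import AlleleCountMatrix, CoverageTrack, Site
from .io_formats import GeneModel

__all__ = [
    "SimConfig",
    "SampleSpec",
    "SimTruth",
    "simulate_host_tree",
    "simulate_symbiont_history",
    "simulate_sequences_and_counts",
    "simulate_gene_models",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_hosts: int = 12
    birth_rate: float = 1.0
    switch_rate: float = 0.0  # expected switches per symbiont branch
    loss_prob: float = 0.0  # per newly created symbiont branch
    variant_density: float = 3.0  # variants per kb
    genome_length: int = 200_000
    depth_lambda: float = 50.0
    error_rate: float = 0.01
    indel_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts < 2:
            raise ValueError("n_hosts must be >= 2")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        for name in ("birth_rate", "switch_rate", "loss_prob", "variant_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SampleSpec:
    """Composition of one sequenced sample.

    ``members`` lists (symbiont tip, weight) pairs; an empty list means the
    symbiont is absent from this sample. ``coinfection`` gives (depth_major,
    depth_minor) for a two-strain sample (members must then have length 2).
    """

    name: str
    members: list[tuple[str, float]] = field(default_factory=list)
    coinfection: tuple[float, float] | None = None


@dataclass
class SimTruth:
    host_tree: dendropy.Tree | None
    symbiont_tree: dendropy.Tree
    tip_mapping: dict[str, str]
    event_counts: dict[str, int]
    ref_seq: str
    sites: list[Site]
    tip_alleles: dict[str, np.ndarray]  # per symbiont tip: allele idx per site
    samples: list[SampleSpec]
    true_site_mask: np.ndarray  # True where a site is a real mutation


# ---------------------------------------------------------------------------
# Host tree (Yule)
# ---------------------------------------------------------------------------

def simulate_host_tree(
    n_hosts: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Ultrametric Yule tree with tips host_001..host_N (reproducible)."""
    if n_hosts < 2:
        raise ValueError("n_hosts must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    birth_time: dict[int, float] = {0: 0.0}
    children: dict[int, list[int]] = {0: []}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n_hosts:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        for _ in range(2):
            birth_time[next_id] = t
            children[next_id] = []
            children[parent].append(next_id)
            active.append(next_id)
            next_id += 1
    t += rng.exponential(1.0 / (birth_rate * n_hosts))

    tns = dendropy.TaxonNamespace()
    label_counter = [0]

    # child edge length = (child's own split time, or the present) minus the
    # child's birth time
    def build(nid: int) -> dendropy.Node:
        node = dendropy.Node()
        if children[nid]:
            for c in children[nid]:
                child = build(c)
                node.add_child(child)
                end = birth_time[children[c][0]] if children[c] else t
                child.edge.length = end - birth_time[c]
        else:
            label_counter[0] += 1
            node.taxon = tns.new_taxon(f"host_{label_counter[0]:03d}")
        return node

    root = build(0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Symbiont history on the host tree
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("time", "children", "host")

    def __init__(self, time: float, children: list, host: str | None = None):
        self.time = time
        self.children = children
        self.host = host  # set on tips only


def _node_times(tree: dendropy.Tree) -> dict[int, float]:
    times = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            times[id(node)] = times[id(node.parent_node)] + (node.edge.length or 0.0)
    return times


def simulate_symbiont_history(
    host: dendropy.Tree,
    switch_rate: float = 0.0,
    loss_prob: float = 0.0,
    seed: int | None = None,
    max_retries: int = 100,
) -> tuple[dendropy.Tree, dict[str, str], dict[str, int]]:
    """Co-diverging symbiont history with host switches and losses.

    The symbiont cospeciates at every host speciation it reaches. While it
    occupies a host edge, switch events arrive as a Poisson process whose
    expectation over a mean-length edge is ``switch_rate``; a switch is a
    bifurcation where one daughter jumps to a uniformly chosen
    contemporaneous foreign host edge. Every newly created branch dies
    immediately with probability ``loss_prob`` (a loss). Returns the realized
    symbiont tree, tip mapping and raw event tallies.
    """
    times = _node_times(host)
    edges: list[tuple[dendropy.Node, float, float]] = []  # (child, t0, t1)
    for node in host.preorder_node_iter():
        if node.parent_node is not None:
            edges.append(
                (node, times[id(node.parent_node)], times[id(node)])
            )
    mean_edge = float(np.mean([t1 - t0 for _, t0, t1 in edges])) if edges else 0.0

    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(attempt + 1)[-1]
            if seed is not None
            else None
        )
        counts = {"cospeciation": 0, "host_switch": 0, "loss": 0}

        def survives() -> bool:
            alive = rng.random() >= loss_prob
            if not alive:
                counts["loss"] += 1
            return alive

        def descend(host_child: dendropy.Node, t0: float) -> _Lineage | None:
            t1 = times[id(host_child)]
            if switch_rate > 0 and mean_edge > 0 and t1 > t0:
                n_sw = rng.poisson(switch_rate * (t1 - t0) / mean_edge)
                sw_times = np.sort(rng.uniform(t0, t1, n_sw)).tolist()
            else:
                sw_times = []
            return _segment(host_child, t0, sw_times)

        def _segment(
            host_child: dendropy.Node, t0: float, sw_times: list[float]
        ) -> _Lineage | None:
            if sw_times:
                ts = sw_times[0]
                targets = [
                    e for e in edges
                    if e[1] < ts <= e[2] and e[0] is not host_child
                ]
                if not targets:
                    return _segment(host_child, t0, sw_times[1:])
                counts["host_switch"] += 1
                target = targets[int(rng.integers(len(targets)))]
                jump = descend(target[0], ts) if survives() else None
                cont = (
                    _segment(host_child, ts, sw_times[1:]) if survives() else None
                )
                kids = [k for k in (cont, jump) if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                return _Lineage(ts, kids)
            t1 = times[id(host_child)]
            if host_child.is_leaf():
                return _Lineage(t1, [], host=host_child.taxon.label)
            daughters = []
            attempted = 0
            for c in host_child.child_nodes():
                if survives():
                    attempted += 1
                    sub = descend(c, t1)
                    if sub is not None:
                        daughters.append(sub)
            if attempted == 2:
                counts["cospeciation"] += 1
            if not daughters:
                return None
            if len(daughters) == 1:
                return daughters[0]
            return _Lineage(t1, daughters)

        # the root lineage cospeciates at the host root immediately
        root_node = host.seed_node
        t_root = times[id(root_node)]
        daughters = []
        attempted = 0
        for c in root_node.child_nodes():
            if survives():
                attempted += 1
                sub = descend(c, t_root)
                if sub is not None:
                    daughters.append(sub)
        if attempted == 2:
            counts["cospeciation"] += 1
        if not daughters:
            continue
        lineage = daughters[0] if len(daughters) == 1 else _Lineage(t_root, daughters)
        return _lineage_to_tree(lineage, counts)
    raise RuntimeError(f"all symbiont lineages lost in {max_retries} attempts")


def _lineage_to_tree(
    root: _Lineage, counts: dict[str, int]
) -> tuple[dendropy.Tree, dict[str, str], dict[str, int]]:
    tns = dendropy.TaxonNamespace()
    mapping: dict[str, str] = {}
    host_seen: dict[str, int] = {}

    def build(lin: _Lineage) -> dendropy.Node:
        node = dendropy.Node()
        if not lin.children:
            host = lin.host
            host_seen[host] = host_seen.get(host, 0) + 1
            label = host if host_seen[host] == 1 else f"{host}_s{host_seen[host]}"
            node.taxon = tns.new_taxon(label)
            mapping[label] = host
        for ch in lin.children:
            child = build(ch)
            node.add_child(child)
            child.edge.length = ch.time - lin.time
        return node

    seed = build(root)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = seed
    tree.is_rooted = True
    return tree, mapping, counts


# ---------------------------------------------------------------------------
# Sequences and allele counts
# ---------------------------------------------------------------------------

def _place_mutations(
    symbiont: dendropy.Tree, cfg: SimConfig, rng: np.random.Generator, ref: np.ndarray
) -> tuple[list[Site], dict[str, np.ndarray], np.ndarray]:
    """Mutations on branches -> biallelic sites + per-tip allele vectors."""
    L = cfg.genome_length
    n_mut = rng.poisson(cfg.variant_density * L / 1000.0)
    if n_mut > L // 8:
        raise ValueError("variant density too high for genome length")
    # keep >= 4 bp spacing so indel spans never collide
    positions = np.sort(rng.choice(L - 8, size=min(n_mut * 2, (L - 8) // 8), replace=False))
    keep = [int(positions[0])] if len(positions) else []
    for p in positions[1:]:
        if p - keep[-1] >= 8:
            keep.append(int(p))
        if len(keep) == n_mut:
            break
    pos_list = keep

    branches = [
        nd for nd in symbiont.preorder_node_iter() if nd.parent_node is not None
    ]
    tips_below: list[list[str]] = [
        [leaf.taxon.label for leaf in nd.leaf_iter()] for nd in branches
    ]
    all_tips = [leaf.taxon.label for leaf in symbiont.leaf_node_iter()]

    sites: list[Site] = []
    carriers: list[list[str]] = []
    for pos in pos_list:
        b = int(rng.integers(len(branches))) if branches else 0
        ref_base = str(_BASES[ref[pos]])
        if rng.random() < cfg.indel_fraction:
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion of k bases after the anchor
                ref_allele = "".join(_BASES[ref[pos:pos + k + 1]])
                alt_allele = ref_base
            else:  # insertion of k random bases after the anchor
                ref_allele = ref_base
                alt_allele = ref_base + "".join(
                    rng.choice(_BASES, size=k)
                )
        else:  # Jukes-Cantor substitution
            others = [b_ for b_ in "ACGT" if b_ != ref_base]
            ref_allele = ref_base
            alt_allele = others[int(rng.integers(3))]
        sites.append(Site("sym", pos, ref_allele, (alt_allele,)))
        carriers.append(tips_below[b] if branches else all_tips)

    order = np.argsort([s.position for s in sites])
    sites = [sites[i] for i in order]
    carriers = [carriers[i] for i in order]
    tip_alleles = {t: np.zeros(len(sites), dtype=np.int64) for t in all_tips}
    for i, tips in enumerate(carriers):
        for t in tips:
            tip_alleles[t][i] = 1
    return sites, tip_alleles, np.array([s.position for s in sites], dtype=np.int64)


def simulate_sequences_and_counts(
    symbiont: dendropy.Tree,
    cfg: SimConfig,
    samples: Sequence[SampleSpec] | None = None,
    seed: int | None = None,
    host: dendropy.Tree | None = None,
    tip_mapping: dict[str, str] | None = None,
    event_counts: dict[str, int] | None = None,
) -> tuple[AlleleCountMatrix, dict[str, CoverageTrack], SimTruth]:
    """Allele counts, coverage tracks and full truth for a strain tree.

    Default sample design: one individual sample per symbiont tip, named
    after the tip, weight 1. With ``error_rate == 0`` every emitted site is
    a true mutation and carries no spurious alleles.
    """
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    L = cfg.genome_length
    ref = rng.integers(0, 4, L)
    sites, tip_alleles, site_pos = _place_mutations(symbiont, cfg, rng, ref)
    tips = list(tip_alleles)
    if samples is None:
        samples = [SampleSpec(t, [(t, 1.0)]) for t in tips]

    # coverage tracks (component tracks kept for coinfection samples)
    tracks: dict[str, CoverageTrack] = {}
    comp_tracks: dict[str, list[np.ndarray]] = {}
    for spec in samples:
        if not spec.members:
            depth = np.zeros(L, dtype=np.int64)
            comp_tracks[spec.name] = []
        elif spec.coinfection is not None:
            if len(spec.members) != 2:
                raise ValueError("coinfection sample needs exactly 2 members")
            major, minor = spec.coinfection
            t1 = rng.poisson(major, L)
            t2 = rng.poisson(minor, L)
            comp_tracks[spec.name] = [t1, t2]
            depth = t1 + t2
        else:
            depth = rng.poisson(cfg.depth_lambda, L)
            comp_tracks[spec.name] = [depth]
        tracks[spec.name] = CoverageTrack(spec.name, "sym", depth)

    # error-only candidate sites (caller-evidence proxy: >= 3 reads of one
    # spurious allele in some sample)
    err_sites: list[Site] = []
    err_depths: list[np.ndarray] = []
    true_pos = set(int(p) for p in site_pos)
    if cfg.error_rate > 0:
        err_counts = {}
        cand = np.zeros(L, dtype=bool)
        for spec in samples:
            e = rng.binomial(tracks[spec.name].depth, cfg.error_rate)
            err_counts[spec.name] = e
            cand |= e >= 3
        cand[list(true_pos)] = False
        for pos in np.flatnonzero(cand):
            per_sample = np.zeros((len(samples), 3), dtype=np.int64)
            for j, spec in enumerate(samples):
                e = int(err_counts[spec.name][pos])
                if e:
                    per_sample[j] = rng.multinomial(e, [1 / 3] * 3)
            if per_sample.max() < 3:
                continue
            alt_slot = int(per_sample.sum(axis=0).argmax())
            ref_base = str(_BASES[ref[pos]])
            others = [b for b in "ACGT" if b != ref_base]
            d = np.zeros((len(samples), 2), dtype=np.int64)
            for j, spec in enumerate(samples):
                total = int(tracks[spec.name].depth[pos])
                errs = int(err_counts[spec.name][pos])
                d[j, 0] = total - errs
                d[j, 1] = per_sample[j, alt_slot]
            err_sites.append(Site("sym", int(pos), ref_base, (others[alt_slot],)))
            err_depths.append(d)

    # depths at true variant sites
    true_depths: list[np.ndarray] = []
    for i, site in enumerate(sites):
        d = np.zeros((len(samples), site.n_alleles), dtype=np.int64)
        for j, spec in enumerate(samples):
            if not spec.members:
                continue
            pos = site.position
            if spec.coinfection is not None:
                member_reads = [int(ct[pos]) for ct in comp_tracks[spec.name]]
            else:
                total = int(tracks[spec.name].depth[pos])
                if len(spec.members) == 1:
                    member_reads = [total]
                else:
                    w = np.array([w_ for _, w_ in spec.members], dtype=float)
                    member_reads = rng.multinomial(total, w / w.sum()).tolist()
            for (tip, _), r in zip(spec.members, member_reads):
                a = int(tip_alleles[tip][i])
                if cfg.error_rate > 0 and r:
                    e = rng.binomial(r, cfg.error_rate)
                else:
                    e = 0
                d[j, a] += r - e
                if e:
                    wrong = [x for x in range(site.n_alleles) if x != a]
                    spread = rng.multinomial(e, [1 / len(wrong)] * len(wrong))
                    for x, cnt in zip(wrong, spread):
                        d[j, x] += cnt
        true_depths.append(d)

    # merge true + error sites in coordinate order
    merged = sorted(
        [(s, d, True) for s, d in zip(sites, true_depths)]
        + [(s, d, False) for s, d in zip(err_sites, err_depths)],
        key=lambda t: (t[0].replicon, t[0].position),
    )
    all_sites = [t[0] for t in merged]
    all_depths = [t[1] for t in merged]
    true_mask = np.array([t[2] for t in merged], dtype=bool)
    sample_names = [s.name for s in samples]
    matrix = AlleleCountMatrix(all_sites, sample_names, all_depths)

    # truth allele vectors on the merged site list (error sites -> ref)
    full_tip_alleles = {}
    true_idx = np.flatnonzero(true_mask)
    for t in tips:
        v = np.zeros(len(all_sites), dtype=np.int64)
        v[true_idx] = tip_alleles[t]
        full_tip_alleles[t] = v

    ref_seq = "".join(_BASES[ref])
    truth = SimTruth(
        host_tree=host,
        symbiont_tree=symbiont,
        tip_mapping=tip_mapping or {},
        event_counts=event_counts or {},
        ref_seq=ref_seq,
        sites=all_sites,
        tip_alleles=full_tip_alleles,
        samples=list(samples),
        true_site_mask=true_mask,
    )
    return matrix, tracks, truth


def simulate_gene_models(
    genome_length: int,
    n_genes: int = 20,
    gene_length: tuple[int, int] = (300, 900),
    seed: int | None = None,
) -> list[GeneModel]:
    """Random non-overlapping genes with random strands."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(n_genes):
        gap = int(rng.integers(50, 200))
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        start = cursor + gap
        end = start + length
        if end > genome_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{i + 1:04d}", "sym", start, end, strand))
        cursor = end
    return genes


def simulate_dataset(
    cfg: SimConfig, seed: int | None = None
) -> tuple[AlleleCountMatrix, dict[str, CoverageTrack], SimTruth]:
    """Full dataset: host tree, symbiont history, counts and truth.

    Samples are the host tips; a host with no symbiont lineage yields an
    uninfected (all-zero coverage) sample, a host reached by one or more
    lineages is sequenced with its first strain.
    """
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    s_host, s_hist, s_pick, s_seq = (
        int(c.generate_state(1)[0]) for c in ss.spawn(4)
    )
    host = simulate_host_tree(cfg.n_hosts, cfg.birth_rate, s_host)
    symbiont, mapping, events = simulate_symbiont_history(
        host, cfg.switch_rate, cfg.loss_prob, s_hist
    )
    by_host: dict[str, list[str]] = {}
    for tip, h in mapping.items():
        by_host.setdefault(h, []).append(tip)
    pick_rng = np.random.default_rng(s_pick)
    samples = []
    for leaf in host.leaf_node_iter():
        h = leaf.taxon.label
        strains = sorted(by_host.get(h, []))
        # a co-occupied host is sequenced with one uniformly chosen strain
        # (the first lineage to arrive is often the vertical one, so taking
        # it deterministically would bias toward congruence)
        members = (
            [(strains[int(pick_rng.integers(len(strains)))], 1.0)]
            if strains
            else []
        )
        samples.append(SampleSpec(h, members))
    return simulate_sequences_and_counts(
        symbiont, cfg, samples, s_seq, host=host,
        tip_mapping=mapping, event_counts=events,
    )
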