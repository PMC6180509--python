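"""End-to-end orchestration: coverage -> filter -> profiles -> trees ->
coinfection -> reconciliation, with a manifest of produced artifacts.

Config is a plain dict (typically loaded from TOML). Each symbiont entry
names its VCF, a directory of per-sample depth TSVs, and optionally a
reference FASTA + GFF3 (for consensus genes), a homology-mask BED and an
outgroup. The host tree for reconciliation is either given explicitly or
proxied by the primary symbiont's profile NJ tree.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Any, Mapping

import dendropy
import numpy as np

from . import __version__
from .coinfection import collect_polymorphic_sites, fit_depth_mixture
from .model import CoverageTrack
from .coverage_screen import (
    PresenceStatus,
    build_presence_matrix,
    call_presence,
    summarize_coverage,
)
from .cophylogeny import CostScheme, cospeciation_test, prune_unusable_tips
from .io_formats import (
    FormatError,
    read_bed_intervals,
    read_coverage,
    read_fasta,
    read_gene_models,
    read_tree,
    read_vcf,
    write_fasta,
    write_tree,
    write_vcf,
)
from .profile_phylogeny import (
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    root_with_outgroup,
    ultrametrize_grafen,
)
from .strain_profiles import (
    build_profiles,
    deduplicate_profiles,
    exclude_ambiguous_samples,
    apply_profile_to_genes,
    write_profiles,
)
from .variant_filter import FilterConfig, filter_cascade

log = logging.getLogger("holostrain")

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable hash of a config mapping (key order independent)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**32)


def _ensure_bifurcating_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root an unrooted (trifurcating-seed) tree for reconciliation."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) != 2:
        try:
            t.reroot_at_midpoint(update_bipartitions=False)
        except (AssertionError, ValueError):
            pass  # degenerate lengths: fall back to the longest-edge split
    if len(t.seed_node.child_nodes()) != 2:
        # midpoint fell exactly on a node: split the longest child edge
        child = max(
            t.seed_node.child_nodes(), key=lambda c: c.edge.length or 0.0
        )
        length = child.edge.length or 0.0
        t.reroot_at_edge(child.edge, update_bipartitions=False)
        for ch in t.seed_node.child_nodes():
            ch.edge.length = length / 2
    t.is_rooted = True
    return t


def run_pipeline(config: Mapping[str, Any], out_dir: str) -> dict[str, Any]:
    """Run every stage for every configured symbiont; return the manifest.

    Symbionts failing the analysable gate (no sample above 10x homogeneous
    coverage) are recorded and skipped, never fatal. When no host tree is
    given, the primary symbiont's NJ tree (ultrametrized) is the host proxy
    for every secondary symbiont's reconciliation.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config.get("seed", 0))
    fcfg = FilterConfig(
        min_alt_reads=int(config.get("min_alt_reads", 4)),
        min_alt_freq=float(config.get("min_alt_freq", 0.10)),
        quantile_frac=float(config.get("quantile_frac", 0.75)),
        high_factor=float(config.get("high_factor", 5.0)),
    )
    n_boot = int(config.get("bootstrap", 0))
    n_perm = int(config.get("n_perm", 500))
    symbionts = config.get("symbionts")
    if not symbionts:
        raise ValueError("config has no [symbionts.*] entries")
    for name, sc in symbionts.items():
        for key in ("vcf", "depth_dir", "genome_length"):
            if key not in sc:
                raise ValueError(f"symbiont {name!r}: missing mandatory key {key!r}")
        for key in ("vcf", "depth_dir"):
            if not os.path.exists(sc[key]):
                raise FileNotFoundError(f"symbiont {name!r}: {sc[key]} not found")

    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config_hash(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "symbionts": {},
    }
    trees: dict[str, dendropy.Tree] = {}
    presence: dict[str, dict[str, PresenceStatus]] = {}

    for name, sc in symbionts.items():
        entry: dict[str, Any] = {"outputs": {}}
        manifest["symbionts"][name] = entry
        sdir = os.path.join(out_dir, name)
        os.makedirs(sdir, exist_ok=True)
        length = int(sc["genome_length"])

        matrix = read_vcf(sc["vcf"])
        entry["n_sites_raw"] = matrix.n_sites
        entry["n_samples"] = matrix.n_samples

        calls = []
        for sample in matrix.samples:
            path = os.path.join(sc["depth_dir"], f"{sample}.tsv")
            try:
                track = read_coverage(path, length, sample=sample)
            except FormatError:  # empty file: the symbiont got no reads
                track = CoverageTrack(sample, name, np.zeros(length, dtype=np.int64))
            calls.append(call_presence(summarize_coverage(track, symbiont=name)))
        presence[name] = {c.sample: c.status for c in calls}
        pm = build_presence_matrix(calls)
        pm_path = os.path.join(sdir, "presence.tsv")
        pm.to_csv(pm_path, sep="\t")
        entry["outputs"]["presence"] = pm_path

        analysable = [
            c.sample for c in calls if c.status == PresenceStatus.ANALYSABLE
        ]
        entry["n_analysable"] = len(analysable)
        if not analysable:
            entry["skipped"] = "no analysable sample (coverage gate)"
            log.warning("symbiont %s skipped: %s", name, entry["skipped"])
            continue

        mask = read_bed_intervals(sc["mask"]) if sc.get("mask") else None
        filtered, report = filter_cascade(
            matrix, fcfg, homology_mask=mask, active_samples=analysable
        )
        entry["n_sites_filtered"] = filtered.n_sites
        entry["filter_report"] = {
            "rare_alleles_zeroed": report.rare_alleles_zeroed,
            "rare_sites_dropped": report.rare_sites_dropped,
            "low_sites": report.low_sites,
            "high_sites": report.high_sites,
            "homology_sites": report.homology_sites,
        }
        fvcf = os.path.join(sdir, "filtered.vcf")
        write_vcf(filtered, fvcf, {name: length})
        entry["outputs"]["filtered_vcf"] = fvcf

        profiles = [
            p for p in build_profiles(filtered) if p.sample in set(analysable)
        ]
        kept, excluded = exclude_ambiguous_samples(profiles)
        entry["excluded_ambiguous"] = excluded
        ptsv = os.path.join(sdir, "profiles.tsv")
        write_profiles(filtered.sites, kept, ptsv)
        entry["outputs"]["profiles"] = ptsv

        if sc.get("ref") and sc.get("gff"):
            reference = read_fasta(sc["ref"])
            genes = read_gene_models(sc["gff"])
            gene_seqs: dict[str, str] = {}
            for p in kept:
                gene_seqs.update(
                    apply_profile_to_genes(reference, genes, filtered.sites, p)
                )
            gfa = os.path.join(sdir, "genes_by_sample.fa")
            write_fasta(gene_seqs, gfa)
            entry["outputs"]["gene_fasta"] = gfa

        reps, groups = deduplicate_profiles(kept)
        entry["duplicate_groups"] = {k: v for k, v in groups.items() if len(v) > 1}
        if len(reps) >= 3 and filtered.n_sites > 0:
            if n_boot > 0 and len(reps) >= 4:
                tree = bootstrap_support(
                    reps, filtered.n_sites, n_boot,
                    _stage_seed(seed, f"boot:{name}"),
                )
            else:
                labels, d = distance_matrix(reps, filtered.n_sites)
                tree = neighbor_joining(labels, d)
            og = sc.get("outgroup")
            if og:
                tree = root_with_outgroup(tree, list(og))
            nwk = os.path.join(sdir, "tree.nwk")
            write_tree(tree, nwk)
            trees[name] = tree
            entry["outputs"]["tree"] = nwk
        else:
            entry["tree_skipped"] = f"only {len(reps)} distinct profiles"

        coinf: dict[str, Any] = {}
        for sample in analysable:
            pss = collect_polymorphic_sites(filtered, sample, fcfg)
            fit = fit_depth_mixture(
                pss, seed=_stage_seed(seed, f"coinf:{name}:{sample}")
            )
            coinf[sample] = {
                "call": fit.call,
                "n_polymorphic": pss.n_sites,
                "means": list(fit.means),
                "reason": fit.reason,
            }
        cpath = os.path.join(sdir, "coinfection.json")
        with open(cpath, "w") as fh:
            json.dump(coinf, fh, indent=2, sort_keys=True)
        entry["outputs"]["coinfection"] = cpath

    # reconciliation against the host tree (explicit or primary proxy)
    primary = config.get("primary")
    host_tree = None
    if config.get("host_tree"):
        host_tree = read_tree(config["host_tree"])
        host_tree.is_rooted = True
    elif primary and primary in trees:
        host_tree = ultrametrize_grafen(_ensure_bifurcating_root(trees[primary]))
    if host_tree is not None:
        manifest["reconciliations"] = {}
        host_tips = {leaf.taxon.label for leaf in host_tree.leaf_node_iter()}
        for name, tree in trees.items():
            if name == primary:
                continue
            phi = {
                leaf.taxon.label: leaf.taxon.label
                for leaf in tree.leaf_node_iter()
                if leaf.taxon.label in host_tips
            }
            if len(phi) < 2:
                continue
            try:
                h2, s2, phi2 = prune_unusable_tips(
                    host_tree, tree, phi, presence.get(name, {})
                )
                s2 = ultrametrize_grafen(_ensure_bifurcating_root(s2))
                res = cospeciation_test(
                    h2, s2, phi2, CostScheme(), n_perm,
                    _stage_seed(seed, f"recon:{name}"),
                )
            except ValueError as exc:
                manifest["reconciliations"][name] = {"error": str(exc)}
                continue
            rj = os.path.join(out_dir, name, "reconciliation.json")
            payload = {
                "cost": res.cost,
                "events": res.event_counts,
                "p_value": res.p_value,
                "n_perm": n_perm,
            }
            with open(rj, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            manifest["reconciliations"][name] = payload
            manifest["symbionts"][name]["outputs"]["reconciliation"] = rj

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
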