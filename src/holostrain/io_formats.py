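"""Readers and writers for external formats.

All internal coordinates are 0-based half-open; VCF and GFF3 (1-based
inclusive) are converted exactly at these boundaries, BED stays 0-based
half-open. Writers emit deterministic ordering so outputs are byte-stable.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlleleCountMatrix, CoverageTrack, Site

__all__ = [
    "FormatError",
    "read_vcf",
    "write_vcf",
    "read_coverage",
    "write_coverage",
    "read_tree",
    "write_tree",
    "tree_from_newick",
    "tree_to_newick",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_tip_mapping",
    "write_tip_mapping",
    "GeneModel",
]


class FormatError(ValueError):
    """Unrecoverable problem with an input file's format or ordering."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> AlleleCountMatrix:
    """Read a multi-sample VCF with per-allele depths into a count matrix.

    Accepts either the modern ``AD`` FORMAT field or the older samtools
    ``DPR``. Multiallelic records are kept as one site. 1-based VCF positions
    become 0-based. Samples with no allelic-depth value at a record are stored
    as all-zero depths with the missing flag set.
    """
    vf = pysam.VariantFile(os.fspath(path))
    try:
        fmt_keys = set(vf.header.formats.keys())
        if "AD" in fmt_keys:
            depth_key = "AD"
        elif "DPR" in fmt_keys:
            depth_key = "DPR"
        else:
            raise FormatError(
                f"{path}: no per-sample allelic depth FORMAT field (AD or DPR)"
            )
        samples = list(vf.header.samples)
        sites: list[Site] = []
        depths: list[np.ndarray] = []
        missing: list[np.ndarray] = []
        last_key: tuple[str, int] | None = None
        for rec in vf:
            key = (rec.chrom, rec.pos)
            if last_key is not None and key <= last_key:
                raise FormatError(
                    f"{path}: unsorted record {rec.chrom}:{rec.pos} "
                    f"(follows {last_key[0]}:{last_key[1]}; records must be "
                    "sorted by replicon then position, no duplicates)"
                )
            last_key = key
            alts = tuple(rec.alts) if rec.alts else ()
            if not alts:
                continue  # monomorphic record carries no variant information
            site = Site(rec.chrom, rec.pos - 1, rec.ref, alts)
            d = np.zeros((len(samples), site.n_alleles), dtype=np.int64)
            miss = np.zeros(len(samples), dtype=bool)
            for j, name in enumerate(samples):
                val = rec.samples[name].get(depth_key)
                if val is None or all(v is None for v in val):
                    miss[j] = True
                    continue
                vals = [0 if v is None else int(v) for v in val]
                if len(vals) != site.n_alleles:
                    raise FormatError(
                        f"{path}: {depth_key} arity {len(vals)} != "
                        f"{site.n_alleles} alleles at {rec.chrom}:{rec.pos} "
                        f"sample {name}"
                    )
                d[j] = vals
            sites.append(site)
            depths.append(d)
            missing.append(miss)
    finally:
        vf.close()
    return AlleleCountMatrix(sites, samples, depths, missing)


def write_vcf(
    m: AlleleCountMatrix,
    path: str | os.PathLike,
    replicon_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a count matrix as a plain-text VCF 4.2 with an AD FORMAT field."""
    replicons: list[str] = []
    for s in m.sites:
        if s.replicon not in replicons:
            replicons.append(s.replicon)
    lines = ["##fileformat=VCFv4.2"]
    for rep in replicons:
        if replicon_lengths and rep in replicon_lengths:
            lines.append(f"##contig=<ID={rep},length={replicon_lengths[rep]}>")
        else:
            lines.append(f"##contig=<ID={rep}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(m.samples)
    )
    for i, site in enumerate(m.sites):
        fields = [
            site.replicon,
            str(site.position + 1),
            ".",
            site.ref,
            ",".join(site.alts),
            ".",
            ".",
            ".",
            "AD",
        ]
        for j in range(m.n_samples):
            if m.missing[i][j]:
                fields.append(".")
            else:
                fields.append(",".join(str(int(v)) for v in m.depths[i][j]))
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coverage tracks (samtools-depth dialect TSV: replicon, 1-based pos, depth)
# ---------------------------------------------------------------------------

def read_coverage(
    path: str | os.PathLike,
    length: int,
    *,
    sample: str | None = None,
    replicon: str | None = None,
) -> CoverageTrack:
    """Read a sparse depth TSV into a dense track; absent positions are 0."""
    if sample is None:
        sample = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    depth = np.zeros(length, dtype=np.int64)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["replicon", "pos", "depth"],
            dtype={"replicon": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        if replicon is None:
            raise FormatError(f"{path}: empty file and no replicon given")
        return CoverageTrack(sample, replicon, depth)
    if df.empty:
        if replicon is None:
            raise FormatError(f"{path}: empty file and no replicon given")
        return CoverageTrack(sample, replicon, depth)
    if replicon is None:
        reps = df["replicon"].unique()
        if len(reps) != 1:
            raise FormatError(
                f"{path}: {len(reps)} replicons present, pass replicon="
            )
        replicon = str(reps[0])
    else:
        df = df[df["replicon"] == replicon]
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise FormatError(f"{path}: negative depth at {bad['replicon']}:{bad['pos']}")
    pos = df["pos"].to_numpy() - 1  # 1-based file -> 0-based
    if len(pos) and (pos.min() < 0 or pos.max() >= length):
        raise FormatError(f"{path}: position outside [1, {length}]")
    depth[pos] = df["depth"].to_numpy()
    return CoverageTrack(sample, replicon, depth)


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write nonzero positions of a track (samtools-depth style, 1-based)."""
    nz = np.nonzero(track.depth)[0]
    with open(path, "w") as fh:
        for p in nz:
            fh.write(f"{track.replicon}\t{p + 1}\t{track.depth[p]}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

_NEWICK_READ_KW = dict(
    schema="newick",
    preserve_underscores=True,
    suppress_internal_node_taxa=True,
)


def tree_from_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, **_NEWICK_READ_KW)
    except Exception as exc:  # dendropy raises several parser error classes
        raise FormatError(f"Newick parse error: {exc}") from exc


def tree_to_newick(tree: dendropy.Tree) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return text.strip() + "\n"


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    with open(path) as fh:
        return tree_from_newick(fh.read())


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA into an ordered {header: sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

class GeneModel:
    """A gene interval (0-based half-open) with strand."""

    __slots__ = ("gene_id", "replicon", "start", "end", "strand")

    def __init__(self, gene_id: str, replicon: str, start: int, end: int, strand: str):
        if not (0 <= start < end):
            raise ValueError(f"gene {gene_id}: bad interval [{start}, {end})")
        if strand not in "+-":
            raise ValueError(f"gene {gene_id}: strand must be + or -")
        self.gene_id = gene_id
        self.replicon = replicon
        self.start = start
        self.end = end
        self.strand = strand

    def __repr__(self) -> str:
        return (
            f"GeneModel({self.gene_id!r}, {self.replicon!r}, "
            f"{self.start}, {self.end}, {self.strand!r})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModel):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.replicon == other.replicon
            and self.start == other.start
            and self.end == other.end
            and self.strand == other.strand
        )


def read_gene_models(path: str | os.PathLike, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file (1-based inclusive -> half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID")
            genes.append(
                GeneModel(gene_id, cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
            )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.replicon}\tholostrain\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open, as-is)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            start, end = int(cols[1]), int(cols[2])
            if start < 0 or end < start:
                raise FormatError(f"{path}:{lineno}: bad interval [{start}, {end})")
            out.append((cols[0], start, end))
    return out


def write_bed_intervals(
    intervals: Sequence[tuple[str, int, int]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for rep, start, end in intervals:
            fh.write(f"{rep}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Tip mapping TSV (symbiont_tip <tab> host_tip)
# ---------------------------------------------------------------------------

def read_tip_mapping(path: str | os.PathLike) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if cols[0] in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate symbiont tip {cols[0]!r}")
            mapping[cols[0]] = cols[1]
    return mapping


def write_tip_mapping(mapping: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")
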