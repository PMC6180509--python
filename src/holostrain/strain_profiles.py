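"""Per-sample strain genotypes (variant profiles) and gene-sequence synthesis.

A variant profile records, for every filtered site, the most abundant allele
in a sample. When the maximum depth is tied the reference allele is kept and
the site is flagged; samples in which more than 5% of variable sites are tied
get excluded. After the filter cascade every retained site carries a
surviving alternative allele in at least one sample, so all profile sites
count as variable when computing the tie fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel
from .model import AlleleCountMatrix, Site

__all__ = [
    "VariantProfile",
    "build_profile",
    "build_profiles",
    "exclude_ambiguous_samples",
    "deduplicate_profiles",
    "apply_profile_to_genes",
    "write_profiles",
    "read_profiles",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantProfile:
    sample: str
    chosen: np.ndarray = field(repr=False)  # allele index per site, 0 = ref
    tie: np.ndarray = field(repr=False)
    missing: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.chosen = np.asarray(self.chosen, dtype=np.int64)
        self.tie = np.asarray(self.tie, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.chosen.shape == self.tie.shape == self.missing.shape):
            raise ValueError("profile array shapes differ")

    @property
    def n_sites(self) -> int:
        return int(self.chosen.shape[0])

    @property
    def tie_fraction(self) -> float:
        """Fraction of non-missing (variable) sites with tied top alleles."""
        informative = ~self.missing
        if not informative.any():
            return 0.0
        return float(self.tie[informative].mean())

    def key(self) -> tuple[int, ...]:
        """Hashable identity of the chosen-allele vector, missing distinct."""
        return tuple(np.where(self.missing, -1, self.chosen).tolist())


def build_profile(m: AlleleCountMatrix, sample: str) -> VariantProfile:
    """Most-abundant-allele profile of one sample.

    Ties (reference among the maxima, or ties between alternatives) fall
    back to the reference allele with the tie flag set. Zero total depth or
    a missing genotype sets the missing flag.
    """
    j = m.sample_index(sample)
    n = m.n_sites
    chosen = np.zeros(n, dtype=np.int64)
    tie = np.zeros(n, dtype=bool)
    missing = np.zeros(n, dtype=bool)
    for i in range(n):
        if m.missing[i][j]:
            missing[i] = True
            continue
        arr = m.depths[i][j]
        total = int(arr.sum())
        if total == 0:
            missing[i] = True
            continue
        mx = arr.max()
        winners = np.flatnonzero(arr == mx)
        if len(winners) > 1:
            chosen[i] = 0
            tie[i] = True
        else:
            chosen[i] = int(winners[0])
    return VariantProfile(sample, chosen, tie, missing)


def build_profiles(m: AlleleCountMatrix) -> list[VariantProfile]:
    return [build_profile(m, s) for s in m.samples]


def exclude_ambiguous_samples(
    profiles: Sequence[VariantProfile], max_tie_fraction: float = 0.05
) -> tuple[list[VariantProfile], dict[str, str]]:
    """Split profiles into (kept, excluded) on the tie-fraction rule.

    Exclusion is strictly greater than ``max_tie_fraction``: a tie fraction
    of exactly 0.05 is kept.
    """
    kept: list[VariantProfile] = []
    excluded: dict[str, str] = {}
    for p in profiles:
        tf = p.tie_fraction
        if tf > max_tie_fraction:
            excluded[p.sample] = (
                f"tie_fraction {tf:.4f} > {max_tie_fraction:.4f}"
            )
        else:
            kept.append(p)
    return kept, excluded


def deduplicate_profiles(
    profiles: Sequence[VariantProfile],
) -> tuple[list[VariantProfile], dict[str, list[str]]]:
    """Group identical chosen-allele vectors; keep one representative each.

    Missing sites compare as a distinct value. The representative of a group
    is its lexicographically smallest sample ID; the returned map allows
    re-expanding trees built on representatives.
    """
    groups: dict[tuple[int, ...], list[VariantProfile]] = {}
    for p in profiles:
        groups.setdefault(p.key(), []).append(p)
    reps: list[VariantProfile] = []
    group_map: dict[str, list[str]] = {}
    for members in groups.values():
        members = sorted(members, key=lambda p: p.sample)
        reps.append(members[0])
        group_map[members[0].sample] = [p.sample for p in members]
    reps.sort(key=lambda p: p.sample)
    return reps, group_map


def _chosen_variants_for_gene(
    sites: Sequence[Site], profile: VariantProfile, gene: GeneModel
) -> list[tuple[Site, str]]:
    """Non-reference chosen variants whose reference span hits the gene."""
    out: list[tuple[Site, str]] = []
    for i, site in enumerate(sites):
        if site.replicon != gene.replicon:
            continue
        if profile.missing[i] or profile.chosen[i] == 0:
            continue  # missing sites inherit the reference allele
        start, end = site.ref_span
        if start < gene.end and end > gene.start:
            out.append((site, site.alleles[int(profile.chosen[i])]))
    out.sort(key=lambda t: t[0].position, reverse=True)
    return out


def apply_profile_to_genes(
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    sites: Sequence[Site],
    profile: VariantProfile,
) -> dict[str, str]:
    """Synthesize per-sample gene sequences by editing the reference.

    Edits are applied in descending coordinate order so earlier edits do not
    shift later coordinates; minus-strand genes are reverse-complemented
    after editing. Output keys are ``{sample}|{gene_id}``. An indel spanning
    a gene boundary is truncated to the overlap with a warning.
    """
    out: dict[str, str] = {}
    for gene in genes:
        if gene.replicon not in reference:
            raise KeyError(f"gene {gene.gene_id}: unknown replicon {gene.replicon!r}")
        seq = reference[gene.replicon][gene.start:gene.end]
        edits = _chosen_variants_for_gene(sites, profile, gene)
        # Overlapping chosen variants should be impossible post-filter.
        for (a, _), (b, _) in zip(edits, edits[1:]):
            if b.ref_span[1] > a.ref_span[0]:
                raise ValueError(
                    f"overlapping chosen variants at {a.replicon}:"
                    f"{b.position} and {a.position}"
                )
        for site, alt in edits:
            start, end = site.ref_span
            lead = max(0, gene.start - start)
            trail = max(0, end - gene.end)
            if lead or trail:
                warnings.warn(
                    f"variant at {site.replicon}:{site.position} spans the "
                    f"boundary of gene {gene.gene_id}; edit truncated"
                )
            rel_start = max(start, gene.start) - gene.start
            rel_end = min(end, gene.end) - gene.start
            if trail:
                # keep only the alt bases aligned to in-gene ref columns
                alt_clip = alt[lead: lead + (rel_end - rel_start)]
            else:
                alt_clip = alt[lead:]
            seq = seq[:rel_start] + alt_clip + seq[rel_end:]
        if gene.strand == "-":
            seq = _revcomp(seq)
        out[f"{profile.sample}|{gene.gene_id}"] = seq
    return out


# ---------------------------------------------------------------------------
# Profiles TSV: sample rows, one column per site; "." = missing, trailing "*"
# marks a tie. Column header: replicon:pos1based:ref:alt1|alt2
# ---------------------------------------------------------------------------

def _site_header(site: Site) -> str:
    return f"{site.replicon}:{site.position + 1}:{site.ref}:{'|'.join(site.alts)}"


def _site_from_header(text: str) -> Site:
    replicon, pos, ref, alts = text.rsplit(":", 3)
    return Site(replicon, int(pos) - 1, ref, tuple(alts.split("|")))


def write_profiles(
    sites: Sequence[Site],
    profiles: Sequence[VariantProfile],
    path: str,
) -> None:
    header = ["sample"] + [_site_header(s) for s in sites]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            row = [p.sample]
            for i, site in enumerate(sites):
                if p.missing[i]:
                    cell = "."
                else:
                    cell = site.alleles[int(p.chosen[i])]
                    if p.tie[i]:
                        cell += "*"
                row.append(cell)
            fh.write("\t".join(row) + "\n")


def read_profiles(path: str) -> tuple[list[Site], list[VariantProfile]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    sites = [_site_from_header(h) for h in header[1:]]
    profiles: list[VariantProfile] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        sample = cells[0]
        chosen = np.zeros(len(sites), dtype=np.int64)
        tie = np.zeros(len(sites), dtype=bool)
        missing = np.zeros(len(sites), dtype=bool)
        for i, (site, cell) in enumerate(zip(sites, cells[1:])):
            if cell == ".":
                missing[i] = True
                continue
            if cell.endswith("*"):
                tie[i] = True
                cell = cell[:-1]
            try:
                chosen[i] = site.alleles.index(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: allele {cell!r} not at site {_site_header(site)}"
                ) from None
        profiles.append(VariantProfile(sample, chosen, tie, missing))
    return sites, profiles
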