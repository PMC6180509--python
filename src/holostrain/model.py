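"""Core data model: sites, allele-count matrices and coverage tracks.

Coordinates are 0-based half-open internally; conversion to the 1-based
conventions of VCF/GFF3 happens only in :mod:`holostrain.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Site", "AlleleCountMatrix", "CoverageTrack"]


@dataclass(frozen=True)
class Site:
    """A variant locus: reference allele plus ordered alternative alleles.

    Multiallelic records are kept as one site so that downstream
    most-abundant-allele logic sees every allele of the locus together.
    """

    replicon: str
    position: int  # 0-based
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if not self.ref:
            raise ValueError("empty reference allele")
        if not self.alts:
            raise ValueError(f"site {self.replicon}:{self.position} has no alt alleles")
        seen = {self.ref}
        for a in self.alts:
            if not a:
                raise ValueError("empty alt allele")
            if a in seen:
                raise ValueError(
                    f"duplicate allele {a!r} at {self.replicon}:{self.position}"
                )
            seen.add(a)

    @property
    def alleles(self) -> tuple[str, ...]:
        """Reference allele followed by the alternatives (index 0 = ref)."""
        return (self.ref,) + self.alts

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open interval of reference coordinates consumed by this site."""
        return self.position, self.position + len(self.ref)


class AlleleCountMatrix:
    """Per-(site, sample, allele) read depths for one symbiont genome.

    ``depths[i]`` is an int array of shape ``(n_samples, sites[i].n_alleles)``.
    ``missing[i]`` flags samples with no genotype data at site *i*; a missing
    sample always carries all-zero depths, but zero depth alone does not imply
    missingness.
    """

    def __init__(
        self,
        sites: Sequence[Site],
        samples: Sequence[str],
        depths: Sequence[np.ndarray],
        missing: Sequence[np.ndarray] | None = None,
    ) -> None:
        self.sites: list[Site] = list(sites)
        self.samples: list[str] = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        n = len(self.samples)
        if len(depths) != len(self.sites):
            raise ValueError("depths length does not match sites")
        self.depths: list[np.ndarray] = []
        for site, d in zip(self.sites, depths):
            arr = np.asarray(d, dtype=np.int64)
            if arr.shape != (n, site.n_alleles):
                raise ValueError(
                    f"depth shape {arr.shape} != ({n}, {site.n_alleles}) "
                    f"at {site.replicon}:{site.position}"
                )
            if (arr < 0).any():
                raise ValueError("negative depth")
            self.depths.append(arr)
        if missing is None:
            self.missing = [np.zeros(n, dtype=bool) for _ in self.sites]
        else:
            if len(missing) != len(self.sites):
                raise ValueError("missing length does not match sites")
            self.missing = [np.asarray(m, dtype=bool).copy() for m in missing]
            for m in self.missing:
                if m.shape != (n,):
                    raise ValueError("missing mask shape mismatch")
        self._check_sorted()

    def _check_sorted(self) -> None:
        keys = [(s.replicon, s.position) for s in self.sites]
        for prev, cur in zip(keys, keys[1:]):
            if cur <= prev:
                raise ValueError(f"sites not sorted/unique at {cur[0]}:{cur[1]}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def total_depth(self, i: int) -> np.ndarray:
        """Total read depth per sample at site i (sum over alleles)."""
        return self.depths[i].sum(axis=1)

    def total_depth_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) matrix of total per-sample depths."""
        if not self.sites:
            return np.zeros((0, self.n_samples), dtype=np.int64)
        return np.stack([self.total_depth(i) for i in range(self.n_sites)])

    def subset_sites(self, indices: Iterable[int]) -> "AlleleCountMatrix":
        idx = list(indices)
        return AlleleCountMatrix(
            [self.sites[i] for i in idx],
            self.samples,
            [self.depths[i].copy() for i in idx],
            [self.missing[i].copy() for i in idx],
        )

    def copy(self) -> "AlleleCountMatrix":
        return self.subset_sites(range(self.n_sites))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and all(np.array_equal(a, b) for a, b in zip(self.depths, other.depths))
            and all(np.array_equal(a, b) for a, b in zip(self.missing, other.missing))
        )

    def __repr__(self) -> str:
        return (
            f"AlleleCountMatrix({self.n_sites} sites x {self.n_samples} samples)"
        )


@dataclass
class CoverageTrack:
    """Dense per-position read depth for one sample on one replicon."""

    sample: str
    replicon: str
    depth: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise ValueError("negative depth in coverage track")

    def __len__(self) -> int:
        return int(self.depth.shape[0])
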