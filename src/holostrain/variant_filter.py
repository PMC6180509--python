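"""Four-rule filtering cascade turning raw allele counts into trusted variants.

Order is canonical: (1) per-sample rare-allele removal (alt alleles with
fewer than ``min_alt_reads`` reads or below ``min_alt_freq`` frequency are
zeroed; both thresholds are strict "less than", so depth 4 and frequency
exactly 10% survive), (2) low/high extreme-coverage site masks relative to
each sample's median variant-site depth, (3) an externally computed homology
mask (BED, 0-based half-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AlleleCountMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_rare_alleles",
    "mask_extreme_coverage",
    "apply_homology_mask",
    "filter_cascade",
    "sample_median_depths",
]


@dataclass(frozen=True)
class FilterConfig:
    min_alt_reads: int = 4
    min_alt_freq: float = 0.10
    quantile_frac: float = 0.75
    high_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")
        if not (0.0 <= self.min_alt_freq <= 1.0):
            raise ValueError("min_alt_freq outside [0, 1]")
        if not (0.0 < self.quantile_frac <= 1.0):
            raise ValueError("quantile_frac outside (0, 1]")
        if self.high_factor <= 1.0:
            raise ValueError("high_factor must be > 1")


@dataclass
class FilterReport:
    """Per-rule removal counts plus a reason per dropped site."""

    rare_alleles_zeroed: int = 0
    rare_sites_dropped: int = 0
    low_sites: int = 0
    high_sites: int = 0
    homology_sites: int = 0
    reasons: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def sites_dropped(self) -> int:
        return (
            self.rare_sites_dropped
            + self.low_sites
            + self.high_sites
            + self.homology_sites
        )

    def merge(self, other: "FilterReport") -> None:
        self.rare_alleles_zeroed += other.rare_alleles_zeroed
        self.rare_sites_dropped += other.rare_sites_dropped
        self.low_sites += other.low_sites
        self.high_sites += other.high_sites
        self.homology_sites += other.homology_sites
        self.reasons.update(other.reasons)


def filter_rare_alleles(
    m: AlleleCountMatrix,
    cfg: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> AlleleCountMatrix:
    """Zero per-sample alternative alleles below the read/frequency floor.

    Frequency is allele depth over the total site depth in that sample
    (reference included); a sample with zero total depth contributes zero
    frequencies, so its alt alleles are removed. Sites where no sample
    retains any alternative allele are dropped. Reference depths are never
    touched.
    """
    if report is None:
        report = FilterReport()
    new_depths: list[np.ndarray] = []
    keep: list[int] = []
    for i in range(m.n_sites):
        arr = m.depths[i].copy()
        total = arr.sum(axis=1).astype(float)  # (n_samples,)
        alt = arr[:, 1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(total[:, None] > 0, alt / total[:, None], 0.0)
        kill = (alt < cfg.min_alt_reads) | (freq < cfg.min_alt_freq)
        report.rare_alleles_zeroed += int((kill & (alt > 0)).sum())
        alt[kill] = 0
        arr[:, 1:] = alt
        if alt.sum() > 0:
            keep.append(i)
            new_depths.append(arr)
        else:
            site = m.sites[i]
            report.rare_sites_dropped += 1
            report.reasons[(site.replicon, site.position)] = "rare"
    return AlleleCountMatrix(
        [m.sites[i] for i in keep],
        m.samples,
        new_depths,
        [m.missing[i].copy() for i in keep],
    )


def sample_median_depths(
    totals: np.ndarray, active: np.ndarray
) -> np.ndarray:
    """Per-sample median of total depth across variant sites.

    The median of an even number of values is the lower-middle element
    (deterministic integer median, no interpolation). Inactive samples get 0.
    """
    n_sites = totals.shape[0]
    med = np.zeros(totals.shape[1], dtype=np.int64)
    k = (n_sites - 1) // 2
    for j in range(totals.shape[1]):
        if active[j]:
            med[j] = np.partition(totals[:, j], k)[k]
    return med


def mask_extreme_coverage(
    m: AlleleCountMatrix,
    cfg: FilterConfig = FilterConfig(),
    active_samples: Sequence[str] | None = None,
) -> tuple[AlleleCountMatrix, FilterReport]:
    """Drop sites of extreme coverage relative to per-sample medians.

    A site is LOW when its total depth is strictly below the sample median
    for at least ``quantile_frac`` of active samples, HIGH when it is at
    least ``high_factor`` times the median for at least that fraction.
    Samples where the symbiont is absent can be excluded from the
    denominators via ``active_samples``.

    The mask is iterated to a fixed point (medians recomputed after each
    removal round) so that the full cascade is idempotent.
    """
    if m.n_sites < 2:
        raise ValueError("extreme-coverage mask needs at least 2 sites")
    if active_samples is None:
        active = np.ones(m.n_samples, dtype=bool)
    else:
        unknown = set(active_samples) - set(m.samples)
        if unknown:
            raise KeyError(f"unknown samples {sorted(unknown)}")
        active = np.array([s in set(active_samples) for s in m.samples])
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("no active samples")

    report = FilterReport()
    cur = m
    while cur.n_sites >= 2:
        totals = cur.total_depth_matrix().astype(np.int64)
        med = sample_median_depths(totals, active)
        t = totals[:, active]
        ma = med[active].astype(float)
        frac_low = (t < ma).sum(axis=1) / n_active
        frac_high = (t >= cfg.high_factor * ma).sum(axis=1) / n_active
        low = frac_low >= cfg.quantile_frac
        high = (~low) & (frac_high >= cfg.quantile_frac)
        if not (low.any() or high.any()):
            break
        keep = []
        for i, site in enumerate(cur.sites):
            if low[i]:
                report.low_sites += 1
                report.reasons[(site.replicon, site.position)] = "low_coverage"
            elif high[i]:
                report.high_sites += 1
                report.reasons[(site.replicon, site.position)] = "high_coverage"
            else:
                keep.append(i)
        cur = cur.subset_sites(keep)
    return cur, report


def apply_homology_mask(
    m: AlleleCountMatrix,
    mask: Sequence[tuple[str, int, int]],
    report: FilterReport | None = None,
) -> AlleleCountMatrix:
    """Drop sites whose position falls inside any masked interval.

    Intervals are 0-based half-open; an interval on a replicon absent from
    the matrix triggers a warning and is ignored.
    """
    if report is None:
        report = FilterReport()
    known = {s.replicon for s in m.sites}
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for rep, start, end in mask:
        if rep not in known:
            warnings.warn(f"homology mask interval on unknown replicon {rep!r}")
            continue
        by_rep.setdefault(rep, []).append((start, end))
    # Sorted interval starts/ends allow a binary-search containment test.
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for rep, ivals in by_rep.items():
        ivals.sort()
        starts = np.array([a for a, _ in ivals])
        ends = np.maximum.accumulate(np.array([b for _, b in ivals]))
        idx[rep] = (starts, ends)
    keep = []
    for i, site in enumerate(m.sites):
        if site.replicon in idx:
            starts, ends = idx[site.replicon]
            j = int(np.searchsorted(starts, site.position, side="right")) - 1
            if j >= 0 and site.position < ends[j]:
                report.homology_sites += 1
                report.reasons[(site.replicon, site.position)] = "homology"
                continue
        keep.append(i)
    return m.subset_sites(keep)


def filter_cascade(
    m: AlleleCountMatrix,
    cfg: FilterConfig = FilterConfig(),
    homology_mask: Sequence[tuple[str, int, int]] | None = None,
    active_samples: Sequence[str] | None = None,
) -> tuple[AlleleCountMatrix, FilterReport]:
    """Run the full cascade: rare alleles, coverage masks, homology mask."""
    report = FilterReport()
    out = filter_rare_alleles(m, cfg, report)
    if out.n_sites >= 2:
        out, cov_report = mask_extreme_coverage(out, cfg, active_samples)
        report.merge(cov_report)
    if homology_mask:
        out = apply_homology_mask(out, homology_mask, report)
    return out, report
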