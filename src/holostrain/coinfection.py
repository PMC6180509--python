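"""Intra-host coinfection detection from allele-depth distributions.

Samples carrying two symbiont strains show a bimodal read-depth distribution
over intra-sample polymorphic sites (each strain's alleles cluster around its
own depth). A 2-component Poisson mixture is fitted by EM and compared to a
single Poisson by BIC; the two component means estimate the strain depths and
let the two haplotypes be phased site by site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import AlleleCountMatrix
from .strain_profiles import VariantProfile
from .variant_filter import FilterConfig

__all__ = [
    "PolymorphicSiteSet",
    "MixtureFit",
    "collect_polymorphic_sites",
    "fit_depth_mixture",
    "phase_by_depth",
    "contamination_check",
]


@dataclass
class PolymorphicSiteSet:
    """Sites with >= 2 alleles surviving the filter in one sample."""

    sample: str
    n_total_sites: int
    site_index: np.ndarray = field(repr=False)  # indices into the matrix
    major_allele: np.ndarray = field(repr=False)
    minor_allele: np.ndarray = field(repr=False)
    major_depth: np.ndarray = field(repr=False)
    minor_depth: np.ndarray = field(repr=False)
    base_chosen: np.ndarray = field(repr=False)  # full-profile context
    base_missing: np.ndarray = field(repr=False)

    @property
    def n_sites(self) -> int:
        return int(self.site_index.shape[0])

    @property
    def fraction(self) -> float:
        if self.n_total_sites == 0:
            return 0.0
        return self.n_sites / self.n_total_sites

    def pooled_depths(self) -> np.ndarray:
        return np.concatenate([self.major_depth, self.minor_depth])


@dataclass
class MixtureFit:
    k: int
    means: tuple[float, ...]  # descending for k=2
    weights: tuple[float, ...]
    bic: dict[int, float]
    loglik: dict[int, float]
    call: str  # "mono" | "bi"
    reason: str
    n_sites: int


def collect_polymorphic_sites(
    m: AlleleCountMatrix, sample: str, cfg: FilterConfig = FilterConfig()
) -> PolymorphicSiteSet:
    """Sites where >= 2 alleles retain nonzero post-filter depth in a sample.

    Major/minor = top two depths (ties resolved toward the lower allele
    index, i.e. the reference first).
    """
    j = m.sample_index(sample)
    idx, major_a, minor_a, major_d, minor_d = [], [], [], [], []
    base_chosen = np.zeros(m.n_sites, dtype=np.int64)
    base_missing = np.zeros(m.n_sites, dtype=bool)
    for i in range(m.n_sites):
        arr = m.depths[i][j]
        total = int(arr.sum())
        if m.missing[i][j] or total == 0:
            base_missing[i] = True
            continue
        order = np.lexsort((np.arange(len(arr)), -arr))  # depth desc, index asc
        # tied maximum falls back to the reference allele (index 0)
        base_chosen[i] = int(order[0]) if arr[order[0]] > arr[order[1]] else 0
        # an allele counts toward polymorphism only if it would itself pass
        # the rare-allele thresholds (the filter never zeroes the reference,
        # so stray error reads on it must be screened out here)
        qualifies = (arr >= cfg.min_alt_reads) & (arr / total >= cfg.min_alt_freq)
        if int(qualifies.sum()) >= 2:
            qual_order = [a for a in order if qualifies[a]]
            idx.append(i)
            major_a.append(int(qual_order[0]))
            minor_a.append(int(qual_order[1]))
            major_d.append(int(arr[qual_order[0]]))
            minor_d.append(int(arr[qual_order[1]]))
    return PolymorphicSiteSet(
        sample=sample,
        n_total_sites=m.n_sites,
        site_index=np.array(idx, dtype=np.int64),
        major_allele=np.array(major_a, dtype=np.int64),
        minor_allele=np.array(minor_a, dtype=np.int64),
        major_depth=np.array(major_d, dtype=np.int64),
        minor_depth=np.array(minor_d, dtype=np.int64),
        base_chosen=base_chosen,
        base_missing=base_missing,
    )


def _poisson_loglik_hist(values: np.ndarray, counts: np.ndarray, lam: float) -> float:
    lam = max(lam, 1e-12)
    return float(
        np.sum(counts * (values * np.log(lam) - lam - gammaln(values + 1)))
    )


def _fit_two_poisson_em(
    values: np.ndarray,
    counts: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Vectorized-over-restarts EM for a 2-component Poisson mixture.

    Restarts are initialized at seeded random quantile pairs of the pooled
    depths. Returns (means desc, weights, loglik, converged) of the best
    restart.
    """
    total = counts.sum()
    # quantile-pair initializations (low, high), jittered per restart
    q_lo = rng.uniform(0.05, 0.45, n_restarts)
    q_hi = rng.uniform(0.55, 0.95, n_restarts)
    cum = np.cumsum(counts) / total
    lam = np.empty((n_restarts, 2))
    lam[:, 0] = values[np.searchsorted(cum, q_hi)]
    lam[:, 1] = values[np.searchsorted(cum, q_lo)]
    lam = np.maximum(lam + rng.uniform(-0.5, 0.5, lam.shape), 0.5)
    w = np.full((n_restarts, 2), 0.5)

    lfact = gammaln(values + 1)
    prev_ll = np.full(n_restarts, -np.inf)
    live = np.ones(n_restarts, dtype=bool)
    converged = np.zeros(n_restarts, dtype=bool)
    ll = prev_ll.copy()
    for _ in range(max_iter):
        if not live.any():
            break
        lam_l = np.maximum(lam[live], 1e-9)  # (R, 2)
        logp = (
            values[None, None, :] * np.log(lam_l)[:, :, None]
            - lam_l[:, :, None]
            - lfact[None, None, :]
            + np.log(np.maximum(w[live], 1e-300))[:, :, None]
        )  # (R, 2, B)
        norm = logsumexp(logp, axis=1)  # (R, B)
        ll_live = (norm * counts[None, :]).sum(axis=1)
        resp = np.exp(logp - norm[:, None, :])  # (R, 2, B)
        wc = resp * counts[None, None, :]
        comp_n = wc.sum(axis=2)  # (R, 2)
        lam_new = (wc * values[None, None, :]).sum(axis=2) / np.maximum(comp_n, 1e-300)
        w_new = comp_n / total
        # relative tolerance: an absolute dLL floor is unreachable in double
        # precision once |LL| is large
        done = np.abs(ll_live - prev_ll[live]) < tol * (1.0 + np.abs(ll_live))
        ll[live] = ll_live
        lam[live] = lam_new
        w[live] = w_new
        prev_ll[live] = ll_live
        live_idx = np.flatnonzero(live)
        converged[live_idx[done]] = True
        live[live_idx[done]] = False
    best = int(np.argmax(ll))
    order = np.argsort(-lam[best])
    return lam[best][order], w[best][order], float(ll[best]), bool(converged[best])


def fit_depth_mixture(
    s: PolymorphicSiteSet,
    min_sites: int = 100,
    seed: int | None = None,
    *,
    minor_only: bool = False,
    n_restarts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 500,
    delta_bic: float = 10.0,
    min_mean_ratio: float = 2.0,
) -> MixtureFit:
    """Fit 1- vs 2-component Poisson mixtures to pooled allele depths.

    The call is *bi* iff the site count reaches ``min_sites``, BIC prefers
    two components by more than ``delta_bic``, and the component means are
    separated by at least ``min_mean_ratio``.
    """
    depths = s.minor_depth if minor_only else s.pooled_depths()
    if s.n_sites < min_sites:
        lam = float(depths.mean()) if len(depths) else 0.0
        return MixtureFit(
            k=1, means=(lam,), weights=(1.0,), bic={}, loglik={},
            call="mono", reason="insufficient sites", n_sites=s.n_sites,
        )
    values, counts = np.unique(depths, return_counts=True)
    values = values.astype(float)
    counts = counts.astype(float)
    n = counts.sum()

    lam1 = float((values * counts).sum() / n)
    ll1 = _poisson_loglik_hist(values, counts, lam1)
    bic1 = -2 * ll1 + 1 * np.log(n)

    rng = np.random.default_rng(seed)
    # stopping rule: |dLL| below tolerance or the iteration cap, whichever
    # first; a non-finite likelihood is true non-convergence
    means2, w2, ll2, _ = _fit_two_poisson_em(
        values, counts, rng, n_restarts, tol, max_iter
    )
    if not np.isfinite(ll2) or not np.all(np.isfinite(means2)):
        raise RuntimeError(
            f"EM diverged (loglik {ll2}, means {means2}, "
            f"{s.n_sites} sites, seed {seed})"
        )
    bic2 = -2 * ll2 + 3 * np.log(n)

    ratio = means2[0] / max(means2[1], 1e-12)
    if bic2 < bic1 - delta_bic and ratio >= min_mean_ratio:
        return MixtureFit(
            k=2,
            means=(float(means2[0]), float(means2[1])),
            weights=(float(w2[0]), float(w2[1])),
            bic={1: float(bic1), 2: float(bic2)},
            loglik={1: ll1, 2: ll2},
            call="bi",
            reason=f"dBIC={bic1 - bic2:.1f}, mean ratio={ratio:.2f}",
            n_sites=s.n_sites,
        )
    return MixtureFit(
        k=1,
        means=(lam1,),
        weights=(1.0,),
        bic={1: float(bic1), 2: float(bic2)},
        loglik={1: ll1, 2: ll2},
        call="mono",
        reason=f"dBIC={bic1 - bic2:.1f}, mean ratio={ratio:.2f}",
        n_sites=s.n_sites,
    )


def _poisson_logpmf(x: np.ndarray, lam: float) -> np.ndarray:
    lam = max(lam, 1e-12)
    return x * np.log(lam) - lam - gammaln(x + 1)


def phase_by_depth(
    s: PolymorphicSiteSet, fit: MixtureFit
) -> tuple[VariantProfile, VariantProfile, np.ndarray]:
    """Split a coinfected sample into two depth-phased haplotypes.

    At each polymorphic site the allele more likely under the high-mean
    component goes to strain 1 and the other to strain 2; monomorphic sites
    assign the single chosen allele to both. Returns (strain1, strain2,
    per-polymorphic-site posterior confidence); exact likelihood ties go
    major-to-strain-1 with confidence 0.5.
    """
    if fit.call != "bi":
        raise ValueError("phase_by_depth requires a bi call")
    hi, lo = fit.means[0], fit.means[1]
    chosen1 = s.base_chosen.copy()
    chosen2 = s.base_chosen.copy()
    missing = s.base_missing.copy()
    tie = np.zeros_like(missing)
    conf = np.zeros(s.n_sites)
    maj = s.major_depth.astype(float)
    mino = s.minor_depth.astype(float)
    # joint likelihood of (major->strain1, minor->strain2) vs the swap
    l_keep = _poisson_logpmf(maj, hi) + _poisson_logpmf(mino, lo)
    l_swap = _poisson_logpmf(mino, hi) + _poisson_logpmf(maj, lo)
    for k in range(s.n_sites):
        i = int(s.site_index[k])
        if l_keep[k] >= l_swap[k]:
            chosen1[i] = s.major_allele[k]
            chosen2[i] = s.minor_allele[k]
        else:
            chosen1[i] = s.minor_allele[k]
            chosen2[i] = s.major_allele[k]
        m = max(l_keep[k], l_swap[k])
        conf[k] = float(
            np.exp(m - m)
            / (1.0 + np.exp(min(l_keep[k], l_swap[k]) - m))
        )
    zeros = np.zeros_like(missing)
    p1 = VariantProfile(f"{s.sample}::strain1", chosen1, zeros.copy(), missing.copy())
    p2 = VariantProfile(f"{s.sample}::strain2", chosen2, zeros.copy(), missing.copy())
    return p1, p2, conf


def contamination_check(
    controls: Mapping[str, PolymorphicSiteSet | None],
    max_polymorphic_fraction: float = 0.001,
) -> bool | None:
    """Clean iff all control genomes show <= the polymorphic-site ceiling.

    A control genome without data yields the result "unknown" (None).
    """
    if not controls or any(v is None for v in controls.values()):
        return None
    return all(
        v.fraction <= max_polymorphic_fraction for v in controls.values()
    )
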