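"""Per-sample, per-symbiont coverage summaries and presence calls.

A symbiont in a sample is *absent* below 1x mean depth, *analysable* above
10x mean depth with homogeneous coverage (at most 90% of positions under
two reads), and *present_low* in between. Both depth thresholds are strict
inequalities; the boundary values 1.0x and 10.0x are present_low.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CoverageTrack

__all__ = [
    "CoverageSummary",
    "PresenceStatus",
    "PresenceCall",
    "summarize_coverage",
    "call_presence",
    "build_presence_matrix",
]

ABSENT_BELOW = 1.0
ANALYSABLE_ABOVE = 10.0
HOMOGENEITY_MAX_FRAC_LT2 = 0.90


@dataclass(frozen=True)
class CoverageSummary:
    sample: str
    symbiont: str
    mean_depth: float
    breadth_ge5: float
    frac_lt2: float
    mean_edit_distance: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.breadth_ge5 <= 1.0):
            raise ValueError("breadth_ge5 outside [0, 1]")
        if not (0.0 <= self.frac_lt2 <= 1.0):
            raise ValueError("frac_lt2 outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("negative mean depth")


class PresenceStatus(str, enum.Enum):
    ABSENT = "absent"
    PRESENT_LOW = "present_low"
    ANALYSABLE = "analysable"


@dataclass(frozen=True)
class PresenceCall:
    sample: str
    symbiont: str
    status: PresenceStatus
    mean_depth: float
    frac_lt2: float


def summarize_coverage(
    track: CoverageTrack,
    symbiont: str | None = None,
    edit_distances: Sequence[int] | None = None,
) -> CoverageSummary:
    """Summarize a coverage track.

    The mean is taken over *all* reference positions (zeros included).
    ``mean_edit_distance`` is the arithmetic mean of the supplied per-read
    values, or None when no edit distances are given.
    """
    if len(track) == 0:
        raise ValueError("empty coverage track")
    d = track.depth
    med = None
    if edit_distances is not None:
        if len(edit_distances) == 0:
            raise ValueError("edit_distances supplied but empty")
        med = float(np.mean(edit_distances))
    return CoverageSummary(
        sample=track.sample,
        symbiont=symbiont if symbiont is not None else track.replicon,
        mean_depth=float(d.mean()),
        breadth_ge5=float((d >= 5).mean()),
        frac_lt2=float((d < 2).mean()),
        mean_edit_distance=med,
    )


def call_presence(summary: CoverageSummary) -> PresenceCall:
    """Classify a (sample, symbiont) pair from its coverage summary."""
    if summary.mean_depth < ABSENT_BELOW:
        status = PresenceStatus.ABSENT
    elif (
        summary.mean_depth > ANALYSABLE_ABOVE
        and summary.frac_lt2 <= HOMOGENEITY_MAX_FRAC_LT2
    ):
        status = PresenceStatus.ANALYSABLE
    else:
        status = PresenceStatus.PRESENT_LOW
    return PresenceCall(
        sample=summary.sample,
        symbiont=summary.symbiont,
        status=status,
        mean_depth=summary.mean_depth,
        frac_lt2=summary.frac_lt2,
    )


_STATUS_CODE = {
    PresenceStatus.ABSENT: "0",
    PresenceStatus.PRESENT_LOW: "low",
    PresenceStatus.ANALYSABLE: "ok",
}


def build_presence_matrix(calls: Iterable[PresenceCall]) -> pd.DataFrame:
    """Samples x symbionts matrix of status strings {0, low, ok}.

    Unobserved (sample, symbiont) pairs are absent. Duplicate calls for the
    same pair are an error.
    """
    seen: dict[tuple[str, str], PresenceStatus] = {}
    samples: list[str] = []
    symbionts: list[str] = []
    for c in calls:
        key = (c.sample, c.symbiont)
        if key in seen:
            raise ValueError(f"duplicate presence call for {key}")
        seen[key] = c.status
        if c.sample not in samples:
            samples.append(c.sample)
        if c.symbiont not in symbionts:
            symbionts.append(c.symbiont)
    mat = pd.DataFrame(
        _STATUS_CODE[PresenceStatus.ABSENT], index=samples, columns=symbionts
    )
    for (sample, symbiont), status in seen.items():
        mat.loc[sample, symbiont] = _STATUS_CODE[status]
    mat.index.name = "sample"
    return mat
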