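"""Depth normalization, background subtraction, site shifting, selection.

Raw deletion counts are normalized by the median read depth over the five
nucleotides downstream of the 3' deletion site (inclusive of the site), so
rates are comparable across positions and samples. The mono-adduct control
sample's rates are then subtracted to remove crosslink-independent,
polymerase-mediated deletions. Finally the 5' site is shifted two
nucleotides in the 3' direction to compensate for where the reverse
transcriptase lands after traversing a crosslink.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable

import numpy as np

from .deletion_detect import Deletion
from .io_formats import AlignmentSegment, ReferenceSequence


@dataclass
class DeletionEntry:
    count: int
    depth: float
    normalized_rate: float
    net_rate: float | None = None


@dataclass
class DeletionProfile:
    """Aggregated deletions of one sample: (five, three) -> entry."""

    sample_id: str
    ref_name: str = ""
    entries: dict[tuple[int, int], DeletionEntry] = field(default_factory=dict)
    depth_vector: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def rate_of(self, key: tuple[int, int]) -> float:
        e = self.entries[key]
        return e.net_rate if e.net_rate is not None else e.normalized_rate


@dataclass
class ShiftConfig:
    """RT-landing correction: ``shift_5p`` moves 5' sites in the 3'
    direction, ``shift_3p`` moves 3' sites in the 5' direction."""

    shift_5p: int = 2
    shift_3p: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.shift_5p <= 5 and 0 <= self.shift_3p <= 5):
            raise ValueError("shifts must lie in [0, 5]")


def compute_depth(
    segments_by_read: Iterable[list[AlignmentSegment]], ref: ReferenceSequence
) -> np.ndarray:
    """Per-position read depth; index 0 is reference position 1.

    A read covers every position from the first to the last reference
    position of its alignment footprint, deleted positions included (a read
    spanning a deletion still evidences sequencing through the locus), and
    counts once per position regardless of how many segments it has.
    """
    n = len(ref)
    diff = np.zeros(n + 1, dtype=np.int64)
    for segs in segments_by_read:
        usable = [s for s in segs if not s.is_secondary and not s.is_reverse]
        if not usable:
            continue
        start = min(s.ref_start for s in usable)
        end = max(s.ref_end for s in usable)
        start = max(start, 1)
        end = min(end, n)
        if start > end:
            continue
        diff[start - 1] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def count_deletions(deletions: Iterable[Deletion]) -> Counter:
    """Collapse per-read deletion records to (five, three) counts."""
    return Counter((d.five_prime_site, d.three_prime_site) for d in deletions)


def normalize_counts(
    counts: Counter | dict[tuple[int, int], int],
    depth_vector: np.ndarray,
    sample_id: str = "",
    ref_name: str = "",
    downstream_window: int = 5,
    include_site: bool = True,
) -> DeletionProfile:
    """Normalize counts by the median depth downstream of the 3' site.

    Depth for a deletion (five, three) is the median of the depth vector
    over [three, three+4] (or [three+1, three+5] when ``include_site`` is
    off), clipped at the reference end; the median is over the available
    positions. Entries whose local depth is zero are excluded.
    """
    n = len(depth_vector)
    profile = DeletionProfile(sample_id=sample_id, ref_name=ref_name,
                              depth_vector=depth_vector)
    for (five, three), count in sorted(counts.items()):
        start = three if include_site else three + 1
        window = depth_vector[start - 1: start - 1 + downstream_window]
        if len(window) == 0:
            continue
        depth = float(median(window.tolist()))
        if depth <= 0:
            continue
        profile.entries[(five, three)] = DeletionEntry(
            count=int(count), depth=depth, normalized_rate=count / depth
        )
    return profile


def subtract_background(
    crosslinked: DeletionProfile, control: DeletionProfile
) -> DeletionProfile:
    """Subtract the mono-adduct control's normalized rates.

    Deletions present only in the crosslinked sample keep their full rate;
    entries whose net rate is not positive are removed; control-only
    entries never appear.
    """
    if control.ref_name and crosslinked.ref_name and \
            control.ref_name != crosslinked.ref_name:
        raise ValueError(
            f"reference mismatch: {crosslinked.ref_name!r} vs {control.ref_name!r}"
        )
    out = DeletionProfile(sample_id=crosslinked.sample_id,
                          ref_name=crosslinked.ref_name,
                          depth_vector=crosslinked.depth_vector)
    for key, e in crosslinked.entries.items():
        bg = control.entries.get(key)
        net = e.normalized_rate - (bg.normalized_rate if bg else 0.0)
        if net <= 0:
            continue
        out.entries[key] = replace(e, net_rate=net)
    return out


def shift_sites(
    profile: DeletionProfile, cfg: ShiftConfig = ShiftConfig()
) -> DeletionProfile:
    """Apply the RT-landing shift: (five, three) -> (five+s5, three-s3).

    Entries whose shifted sites cross (three <= five+1) are dropped and
    tallied on the returned profile's ``entries``-free diagnostics; rates
    are unchanged. When two keys collide after shifting, counts are summed
    and rates combined additively (rates are per-depth counts of the same
    junction population).
    """
    out = DeletionProfile(sample_id=profile.sample_id, ref_name=profile.ref_name,
                          depth_vector=profile.depth_vector)
    for (five, three), e in sorted(profile.entries.items()):
        nf, nt = five + cfg.shift_5p, three - cfg.shift_3p
        if nt <= nf + 1:
            continue
        key = (nf, nt)
        if key in out.entries:
            prev = out.entries[key]
            total = prev.count + e.count
            # depth as count-weighted mean keeps count ~= rate * depth
            new_norm = prev.normalized_rate + e.normalized_rate
            new_net = None
            if prev.net_rate is not None or e.net_rate is not None:
                new_net = (prev.net_rate or 0.0) + (e.net_rate or 0.0)
            depth = total / new_norm if new_norm > 0 else prev.depth
            out.entries[key] = DeletionEntry(total, depth, new_norm, new_net)
        else:
            out.entries[key] = replace(e)
    return out


def select_top_fraction(
    profile: DeletionProfile, fraction: float
) -> DeletionProfile:
    """The ceil(fraction * N) entries with the highest net rate.

    Ties broken by (five, three) ascending for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(profile.entries)
    out = DeletionProfile(sample_id=profile.sample_id, ref_name=profile.ref_name,
                          depth_vector=profile.depth_vector)
    if n == 0:
        return out
    k = math.ceil(fraction * n)
    ranked = sorted(profile.entries.items(),
                    key=lambda kv: (-profile.rate_of(kv[0]), kv[0]))
    for key, e in ranked[:k]:
        out.entries[key] = replace(e)
    return out
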