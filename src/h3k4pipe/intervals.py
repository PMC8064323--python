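"""Library normalization and cross-sample merged-region algebra.

Normalization follows the smallest-library rule: every sample is randomly
downsampled, without replacement, to the tag count of the smallest sample.
Merged regions are the transitive closure of interval overlap across all
samples: each region runs from the most upstream member start to the most
downstream member end, and a single-sample island with no overlap partner
defines a region on its own. Intervals are half-open; book-ended intervals
do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import TagSet
from .islands import Island
from .simulate import substream


def downsample_tags(samples: list[TagSet], seed: int) -> list[TagSet]:
    """Downsample every sample to the smallest library size.

    Sampling is without replacement and deterministic given ``seed`` (each
    sample uses its own substream, so results do not depend on sample
    order). The smallest sample is returned unchanged.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if any(s.total_count == 0 for s in samples):
        raise ValueError("all samples must have at least one tag")
    target = min(s.total_count for s in samples)
    out = []
    for s in samples:
        if s.total_count == target:
            frame = s.fragments.copy()
        else:
            rng = substream(seed, f"downsample:{s.sample_id}")
            idx = np.sort(rng.choice(s.total_count, size=target, replace=False))
            frame = s.fragments.iloc[idx].reset_index(drop=True)
        out.append(TagSet(s.sample_id, s.group, frame))
    return out


@dataclass
class MergedRegion:
    """Cross-sample union interval with per-sample membership."""

    chrom: str
    start: int
    end: int
    member_intervals: dict[str, list[tuple[int, int]]]
    present_in: dict[str, bool] = field(default_factory=dict)
    group_presence: dict[str, bool] = field(default_factory=dict)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> tuple[str, int, int]:
        return self.chrom, self.start, self.end


def merge_regions(
    per_sample_islands: dict[str, list[Island]],
    groups: dict[str, str],
    presence_mode: str = "any",
) -> list[MergedRegion]:
    """Union overlapping islands across samples into merged regions.

    Two intervals overlap iff they share >= 1 bp under half-open semantics;
    overlap is closed transitively, so each input island belongs to exactly
    one region and regions are pairwise disjoint and sorted. A group is
    marked present when any of its samples contributes (``presence_mode``
    "any", the region-level Venn convention) or, stricter, when all of them
    do ("all").
    """
    if presence_mode not in ("any", "all"):
        raise ValueError("presence_mode must be 'any' or 'all'")
    samples = sorted(per_sample_islands)
    events = []
    for sid in samples:
        for isl in per_sample_islands[sid]:
            events.append((isl.chrom, isl.start, isl.end, sid))
    events.sort()

    regions: list[MergedRegion] = []
    cur: MergedRegion | None = None
    for chrom, start, end, sid in events:
        if cur is not None and chrom == cur.chrom and start < cur.end:
            cur.end = max(cur.end, end)
            cur.member_intervals.setdefault(sid, []).append((start, end))
        else:
            cur = MergedRegion(chrom, start, end, {sid: [(start, end)]})
            regions.append(cur)

    group_names = sorted(set(groups.values()))
    agg = any if presence_mode == "any" else all
    for r in regions:
        r.present_in = {sid: sid in r.member_intervals for sid in samples}
        r.group_presence = {
            g: agg(r.present_in[sid] for sid in samples if groups[sid] == g)
            for g in group_names
        }
    return regions


def group_venn(
    regions: list[MergedRegion], group_a: str = "A", group_b: str = "B"
) -> dict[str, int]:
    """Region-level Venn counts: exclusive to each group vs shared.

    A region counts as group-present when any sample of the group
    contributes a member interval.
    """
    counts = {"exclusive_A": 0, "exclusive_B": 0, "shared": 0}
    for r in regions:
        a = r.group_presence.get(group_a, False)
        b = r.group_presence.get(group_b, False)
        if a and b:
            counts["shared"] += 1
        elif a:
            counts["exclusive_A"] += 1
        elif b:
            counts["exclusive_B"] += 1
        else:
            raise ValueError(f"region {r.region_id} present in neither group")
    return counts


def per_chromosome_counts(regions: list[MergedRegion]) -> pd.Series:
    """Number of merged regions per chromosome (sums to the total)."""
    tally: dict[str, int] = {}
    for r in regions:
        tally[r.chrom] = tally.get(r.chrom, 0) + 1
    return pd.Series(tally, dtype=int).sort_index()


def pairwise_overlap_fraction(
    islands_a: list[Island] | list[tuple],
    islands_b: list[Island] | list[tuple],
) -> float:
    """Fraction of a's islands that overlap >= 1 bp of some island in b.

    Asymmetric (a against b); both lists must be internally disjoint.
    """
    a = _as_intervals(islands_a)
    b = _as_intervals(islands_b)
    if not a:
        return 0.0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _, _ in b}:
        ivs = sorted((s, e) for c, s, e in b if c == chrom)
        starts = np.array([s for s, _ in ivs])
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        by_chrom[chrom] = (starts, ends)
    hits = 0
    for chrom, s, e in a:
        if chrom not in by_chrom:
            continue
        starts, maxends = by_chrom[chrom]
        k = np.searchsorted(starts, e, side="left")  # candidates start before e
        if k > 0 and maxends[k - 1] > s:
            hits += 1
    return hits / len(a)


def _as_intervals(items) -> list[tuple[str, int, int]]:
    out = []
    for it in items:
        if isinstance(it, Island):
            out.append((it.chrom, it.start, it.end))
        else:
            c, s, e = it[:3]
            out.append((str(c), int(s), int(e)))
    return out
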