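"""Normalization, merged regions, Venn, per-chromosome, overlap QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from h3k4pipe.islands import Island
from h3k4pipe.intervals import (
    MergedRegion,
    downsample_tags,
    group_venn,
    merge_regions,
    pairwise_overlap_fraction,
    per_chromosome_counts,
)

from conftest import make_tagset


def _island(chrom, start, end):
    return Island(chrom, start, end, 1, 0.0, 1.0, 0.0)


def _random_disjoint_islands(rng, n, chrom="chr1", span=1_000_000):
    """n sorted non-overlapping random islands on one chromosome."""
    points = np.sort(rng.choice(span, size=2 * n, replace=False))
    return [_island(chrom, int(points[2 * i]), int(points[2 * i + 1]))
            for i in range(n)]


class TestDownsample:
    def _samples(self, rng, totals):
        out = []
        for i, n in enumerate(totals):
            starts = rng.integers(0, 999_000, size=n)
            out.append(make_tagset(
                [("chr1", int(s), int(s) + 200) for s in starts],
                sample_id=f"s{i}", group="A"))
        return out

    def test_min_rule(self, rng):
        normed = downsample_tags(self._samples(rng, (100, 80, 120)), seed=1)
        assert [t.total_count for t in normed] == [80, 80, 80]

    def test_smallest_sample_unchanged(self, rng):
        samples = self._samples(rng, (100, 80, 120))
        normed = downsample_tags(samples, seed=1)
        orig = set(map(tuple, samples[1].fragments.itertuples(index=False)))
        kept = set(map(tuple, normed[1].fragments.itertuples(index=False)))
        assert orig == kept

    def test_deterministic_subset_conserving(self, rng):
        samples = self._samples(rng, (100_000, 50_000))
        a = downsample_tags(samples, seed=7)
        b = downsample_tags(samples, seed=7)
        c = downsample_tags(samples, seed=8)
        assert a[0].fragments.equals(b[0].fragments)
        from collections import Counter

        big = Counter(map(tuple, samples[0].fragments.itertuples(index=False)))
        sub_a = Counter(map(tuple, a[0].fragments.itertuples(index=False)))
        sub_c = Counter(map(tuple, c[0].fragments.itertuples(index=False)))
        assert not sub_a - big and not sub_c - big  # multiset inclusion
        assert sub_a != sub_c
        assert a[0].total_count == c[0].total_count == 50_000

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            downsample_tags([], seed=1)


def brute_force_merge(per_sample):
    """Union-find over all pairwise interval overlaps (oracle)."""
    items = [(c, s, e, sid) for sid, isls in per_sample.items()
             for (c, s, e) in [(i.chrom, i.start, i.end) for i in isls]]
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, si, ei, _ = items[i]
            cj, sj, ej, _ = items[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    clusters = {}
    for k in range(len(items)):
        clusters.setdefault(find(k), []).append(items[k])
    out = []
    for members in clusters.values():
        chrom = members[0][0]
        out.append((chrom, min(m[1] for m in members), max(m[2] for m in members),
                    frozenset(m[3] for m in members)))
    return sorted(out)


class TestMergeRegions:
    def test_overlap_merges(self):
        regions = merge_regions(
            {"s1": [_island("chr1", 100, 300)], "s2": [_island("chr1", 250, 400)]},
            {"s1": "A", "s2": "B"},
        )
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (100, 400)
        assert r.present_in == {"s1": True, "s2": True}

    def test_single_sample_defines_region(self):
        regions = merge_regions(
            {"s1": [_island("chr1", 500, 900)], "s2": []},
            {"s1": "A", "s2": "B"},
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (500, 900)
        assert regions[0].present_in == {"s1": True, "s2": False}
        assert regions[0].group_presence == {"A": True, "B": False}

    def test_bookended_do_not_merge(self):
        regions = merge_regions(
            {"s1": [_island("chr1", 100, 200)], "s2": [_island("chr1", 200, 300)]},
            {"s1": "A", "s2": "B"},
        )
        assert len(regions) == 2

    def test_matches_union_find_oracle(self, rng):
        per_sample = {
            f"s{i}": _random_disjoint_islands(rng, 200, span=400_000)
            for i in range(3)
        }
        groups = {"s0": "A", "s1": "A", "s2": "B"}
        regions = merge_regions(per_sample, groups)
        got = sorted(
            (r.chrom, r.start, r.end, frozenset(r.member_intervals)) for r in regions
        )
        assert got == brute_force_merge(per_sample)
        # each input island lands in exactly one region
        n_members = sum(len(v) for r in regions for v in r.member_intervals.values())
        assert n_members == sum(len(v) for v in per_sample.values())

    def test_idempotent(self, rng):
        per_sample = {f"s{i}": _random_disjoint_islands(rng, 100) for i in range(3)}
        groups = {f"s{i}": "A" for i in range(3)}
        regions = merge_regions(per_sample, groups)
        again = merge_regions(
            {"merged": [_island(r.chrom, r.start, r.end) for r in regions]},
            {"merged": "A"},
        )
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regions]


class TestGroupVenn:
    def _region(self, a, b):
        return MergedRegion("chr1", 0, 1, {}, {}, {"A": a, "B": b})

    def test_all_shared(self):
        regions = [self._region(True, True) for _ in range(5)]
        assert group_venn(regions) == {"exclusive_A": 0, "exclusive_B": 0, "shared": 5}

    def test_enumeration(self):
        regions = [self._region(True, False), self._region(False, True),
                   self._region(True, True)]
        assert group_venn(regions) == {"exclusive_A": 1, "exclusive_B": 1, "shared": 1}

    def test_partition_on_random_presence(self, rng):
        regions = []
        expected = {"exclusive_A": 0, "exclusive_B": 0, "shared": 0}
        for _ in range(500):
            a, b = bool(rng.integers(0, 2)), bool(rng.integers(0, 2))
            if not (a or b):
                a = True
            regions.append(self._region(a, b))
            expected["shared" if (a and b) else
                     ("exclusive_A" if a else "exclusive_B")] += 1
        counts = group_venn(regions)
        assert counts == expected
        assert sum(counts.values()) == 500


class TestPerChromosome:
    def test_empty(self):
        assert per_chromosome_counts([]).empty

    def test_tally_matches(self, rng):
        chroms = [f"chr{int(c) + 1}" for c in rng.integers(0, 4, size=200)]
        regions = [MergedRegion(c, 0, 1, {}) for c in chroms]
        counts = per_chromosome_counts(regions)
        assert counts.sum() == 200
        for c in set(chroms):
            assert counts[c] == chroms.count(c)


class TestPairwiseOverlap:
    def test_identical(self, rng):
        a = _random_disjoint_islands(rng, 50)
        assert pairwise_overlap_fraction(a, a) == 1.0

    def test_disjoint(self):
        a = [_island("chr1", 0, 100)]
        b = [_island("chr1", 100, 200)]
        assert pairwise_overlap_fraction(a, b) == 0.0

    def test_matches_quadratic_oracle(self, rng):
        a = _random_disjoint_islands(rng, 150, span=200_000)
        b = _random_disjoint_islands(rng, 150, span=200_000)
        hits = sum(
            any(ia.chrom == ib.chrom and ia.start < ib.end and ib.start < ia.end
                for ib in b)
            for ia in a
        )
        assert pairwise_overlap_fraction(a, b) == pytest.approx(hits / len(a))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
                min_size=1, max_size=40))
def test_merge_idempotent_property(intervals):
    """Merging any interval set twice equals merging it once."""
    islands = sorted((s, s + w) for s, w in intervals)
    per = {"s": []}
    prev_end = -1  # enforce within-sample disjointness as the caller would
    for s, e in islands:
        if s <= prev_end:
            continue
        per["s"].append(_island("chr1", s, e))
        prev_end = e
    first = merge_regions(per, {"s": "A"})
    second = merge_regions(
        {"m": [_island(r.chrom, r.start, r.end) for r in first]}, {"m": "A"}
    )
    assert [(r.start, r.end) for r in first] == [(r.start, r.end) for r in second]


class TestPresenceMode:
    def test_strict_mode_requires_all_samples(self):
        per = {
            "s1": [_island("chr1", 100, 300)],
            "s2": [_island("chr1", 250, 400)],
            "s3": [],
        }
        groups = {"s1": "A", "s2": "A", "s3": "B"}
        loose = merge_regions(per, groups, presence_mode="any")
        strict = merge_regions(per, groups, presence_mode="all")
        assert loose[0].group_presence == {"A": True, "B": False}
        assert strict[0].group_presence == {"A": True, "B": False}
        per["s2"] = []
        groups = {"s1": "A", "s2": "A", "s3": "B"}
        strict = merge_regions(per, groups, presence_mode="all")
        assert strict[0].group_presence["A"] is False

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            merge_regions({"s": []}, {"s": "A"}, presence_mode="some")
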