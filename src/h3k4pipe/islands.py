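"""SICER-style island calling from binned tag counts.

A sample's fragments are assigned to fixed-width bins by midpoint; scoring
windows (default 200 bp) are marked *eligible* when their count exceeds a
permissive Poisson background threshold, eligible windows separated by at
most a gap (default 600 bp) are chained into islands, and island
significance is the Poisson upper-tail probability of the island's tag count
against the genome-wide background rate scaled to the island length,
corrected across islands with Benjamini-Hochberg. Only islands below the FDR
cutoff (default 1e-10) are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeLayout, TagSet

log = logging.getLogger(__name__)

DEFAULT_BIN = 32
DEFAULT_WINDOW = 200
DEFAULT_GAP = 600
DEFAULT_WINDOW_P = 0.2
DEFAULT_FDR = 1e-10


@dataclass
class BinnedCoverage:
    """Per-chromosome fragment-midpoint counts in fixed-width bins."""

    bin_size: int
    counts: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    total_tags: int


@dataclass(frozen=True)
class Island:
    """An enriched interval: score is -log10 of the Poisson tail probability."""

    chrom: str
    start: int
    end: int
    tag_count: int
    score: float
    p: float
    fdr: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("island end must exceed start")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def bin_tags(tags: TagSet, layout: GenomeLayout, bin_size: int = DEFAULT_BIN) -> BinnedCoverage:
    """Count fragment midpoints per ``bin_size`` bin (trailing partial bin kept)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    tags.validate_bounds(layout)
    sizes = layout.sizes()
    counts = {
        c: np.zeros(-(-sizes[c] // bin_size), dtype=np.int64) for c in layout.chrom_names
    }
    for chrom, mids in tags.midpoints().items():
        counts[chrom] = np.bincount(mids // bin_size, minlength=len(counts[chrom])).astype(
            np.int64
        )
    return BinnedCoverage(bin_size, counts, sizes, tags.total_count)


def _window_counts(cov: BinnedCoverage, window: int) -> dict[str, np.ndarray]:
    per_win = window // cov.bin_size
    out = {}
    for chrom, c in cov.counts.items():
        pad = (-len(c)) % per_win
        padded = np.concatenate([c, np.zeros(pad, dtype=c.dtype)]) if pad else c
        out[chrom] = padded.reshape(-1, per_win).sum(axis=1)
    return out


def call_islands(
    cov: BinnedCoverage,
    window: int = DEFAULT_WINDOW,
    gap: int = DEFAULT_GAP,
    window_p: float = DEFAULT_WINDOW_P,
    fdr_cutoff: float = DEFAULT_FDR,
    input_cov: BinnedCoverage | None = None,
) -> list[Island]:
    """Call enriched islands from binned coverage.

    The background rate is ``lambda = total_tags * window / genome_length``;
    when an input (control) coverage is supplied, the expected island count
    is the larger of the global background and the depth-scaled input count
    over the island span.
    """
    genome_len = sum(cov.chrom_lengths.values())
    if genome_len <= 0:
        raise ValueError("zero-length genome")
    if cov.total_tags == 0:
        return []
    if window % cov.bin_size:
        new = -(-window // cov.bin_size) * cov.bin_size
        log.warning("window %d rounded up to %d (multiple of bin size)", window, new)
        window = new
    if gap % window:
        new = -(-gap // window) * window
        log.warning("gap %d rounded up to %d (multiple of window)", gap, new)
        gap = new

    lam = cov.total_tags * window / genome_len
    wc = _window_counts(cov, window)
    in_wc = _window_counts(input_cov, window) if input_cov is not None else None
    in_scale = (
        cov.total_tags / input_cov.total_tags
        if input_cov is not None and input_cov.total_tags > 0
        else 1.0
    )

    raw: list[tuple[str, int, int, int, float]] = []
    for chrom in sorted(wc):
        counts = wc[chrom]
        tail = stats.poisson.sf(counts - 1, lam)
        eligible = np.flatnonzero(tail < window_p)
        if eligible.size == 0:
            continue
        # chain eligible windows whose intervening span is <= gap
        breaks = np.flatnonzero((np.diff(eligible) - 1) * window > gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [eligible.size - 1]))
        for si, ei in zip(starts, ends):
            first, last = int(eligible[si]), int(eligible[ei])
            n_win = last - first + 1
            count = int(counts[first : last + 1].sum())
            expected = lam * n_win
            if in_wc is not None:
                local = float(in_wc[chrom][first : last + 1].sum()) * in_scale
                expected = max(expected, local)
            p = float(stats.poisson.sf(count - 1, expected))
            start = first * window
            end = min((last + 1) * window, cov.chrom_lengths[chrom])
            raw.append((chrom, start, end, count, p))

    if not raw:
        return []
    pvals = np.array([r[4] for r in raw])
    fdr = _benjamini_hochberg(pvals)
    islands = [
        Island(c, s, e, n, -math.log10(max(p, 1e-300)), p, float(q))
        for (c, s, e, n, p), q in zip(raw, fdr)
        if q < fdr_cutoff
    ]
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out
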