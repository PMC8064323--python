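"""Genome layout, gene models and tag sets.

All coordinates are 0-based, half-open (BED convention). A gene's genomic
span is ``[start, end)``; on the plus strand the transcription start site
(TSS) is the span start, on the minus strand it is the half-open span end,
so ``tss < tes`` on ``+`` and ``tss > tes`` on ``-`` when both are read as
genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and sizes of a (synthetic) assembly."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene structure.

    ``exons`` are genomic ``(start, end)`` half-open intervals, sorted and
    non-overlapping, covering positions inside ``[span_start, span_end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")
        prev_end = self.span_start
        for a, b in self.exons:
            if a < prev_end or b <= a or b > self.span_end:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and within the gene span"
                )
            prev_end = b

    @property
    def span_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def span_end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    def promoter(self, halfwidth: int = 1000) -> tuple[int, int]:
        """TSS +/- halfwidth window, genomic coordinates (may need clipping)."""
        return self.tss - halfwidth, self.tss + halfwidth

    def signed_tss_distance(self, pos: int) -> int:
        """Strand-aware distance of ``pos`` from the TSS (negative = upstream)."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


@dataclass
class TagSet:
    """One sample's extended ChIP fragments.

    ``fragments`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open); fragment lengths correspond to in-silico 3'-extended
    sequencing tags (150-250 bp).
    """

    sample_id: str
    group: str
    fragments: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"chrom", "start", "end"}
        if not needed.issubset(self.fragments.columns):
            raise ValueError(f"fragments must have columns {sorted(needed)}")

    @property
    def total_count(self) -> int:
        return int(len(self.fragments))

    def midpoints(self) -> dict[str, np.ndarray]:
        """Sorted fragment midpoints per chromosome."""
        out: dict[str, np.ndarray] = {}
        frag = self.fragments
        mids = ((frag["start"].to_numpy() + frag["end"].to_numpy()) // 2)
        for chrom in sorted(frag["chrom"].unique()):
            m = mids[(frag["chrom"] == chrom).to_numpy()]
            out[str(chrom)] = np.sort(m)
        return out

    def validate_bounds(self, layout: GenomeLayout) -> None:
        sizes = layout.sizes()
        frag = self.fragments
        for chrom, sub in frag.groupby("chrom", sort=False):
            if chrom not in sizes:
                raise ValueError(
                    f"{self.sample_id}: fragment on unknown chromosome {chrom!r}"
                )
            bad = sub[(sub["start"] < 0) | (sub["end"] > sizes[chrom])]
            if len(bad):
                rec = bad.iloc[0]
                raise ValueError(
                    f"{self.sample_id}: fragment outside {chrom} bounds: "
                    f"[{int(rec['start'])}, {int(rec['end'])})"
                )
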