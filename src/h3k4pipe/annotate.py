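"""Genomic feature classification of regions against gene models.

A region is classified by its midpoint against the nearest gene,
strand-aware, into one of nine categories: proximal promoter (0-1 kb
upstream of the TSS), distal promoter (1-3 kb), 5'UTR, exon, intron, 3'UTR,
proximal downstream (0-1 kb past the TES), distal downstream (1-3 kb), or
distal intergenic. In-gene precedence is 5'UTR > 3'UTR > exon > intron
(UTRs are subsets of exons; specific before general). In synthetic gene
models the UTRs are, by convention, the first and last 10% of the gene span.

The 10 kb gene-association margin (genes vs peaks within 10 kb of gene
start/end) is a separate search, :func:`genes_near_peaks`, and does not
create a pie category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout, GeneModel
from .simulate import substream

CATEGORIES = (
    "proximal_promoter",
    "distal_promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "proximal_downstream",
    "distal_downstream",
    "distal_intergenic",
)

PROXIMAL_BP = 1000
DISTAL_BP = 3000
GENE_MARGIN = 10_000
UTR_FRACTION = 0.1


@dataclass(frozen=True)
class RegionAnnotation:
    region: tuple[str, int, int]
    category: str
    gene_id: str | None
    tss_distance: int | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.gene_id is None) != (self.category == "distal_intergenic"):
            raise ValueError("gene_id must be None iff distal_intergenic")


def _classify_against_gene(
    m: int,
    gene: GeneModel,
    proximal: int,
    distal: int,
    utr_fraction: float,
) -> str | None:
    """Category of midpoint ``m`` relative to one gene, or None if outside."""
    s, e = gene.span_start, gene.span_end
    if s <= m < e:
        if gene.strand == "+":
            local = m - s
        else:
            local = e - 1 - m  # distance from the TSS base
        L = e - s
        if local < utr_fraction * L:
            return "five_prime_utr"
        if local >= (1.0 - utr_fraction) * L:
            return "three_prime_utr"
        if any(a <= m < b for a, b in gene.exons):
            return "exon"
        return "intron"
    if gene.strand == "+":
        up_prox = (s - proximal, s)
        up_dist = (s - distal, s - proximal)
        dn_prox = (e, e + proximal)
        dn_dist = (e + proximal, e + distal)
    else:
        up_prox = (e, e + proximal)
        up_dist = (e + proximal, e + distal)
        dn_prox = (s - proximal, s)
        dn_dist = (s - distal, s - proximal)
    if up_prox[0] <= m < up_prox[1]:
        return "proximal_promoter"
    if up_dist[0] <= m < up_dist[1]:
        return "distal_promoter"
    if dn_prox[0] <= m < dn_prox[1]:
        return "proximal_downstream"
    if dn_dist[0] <= m < dn_dist[1]:
        return "distal_downstream"
    return None


def annotate_region(
    region: tuple[str, int, int],
    genes: list[GeneModel],
    proximal: int = PROXIMAL_BP,
    distal: int = DISTAL_BP,
    utr_fraction: float = UTR_FRACTION,
) -> RegionAnnotation:
    """Classify one region by midpoint; ties go to the gene with the
    smallest absolute TSS distance, then lexicographic gene_id."""
    chrom, start, end = region[0], int(region[1]), int(region[2])
    m = (start + end) // 2
    best: tuple[int, str, str, int] | None = None  # |d|, gene_id, category, d
    for g in genes:
        if g.chrom != chrom:
            continue
        cat = _classify_against_gene(m, g, proximal, distal, utr_fraction)
        if cat is None:
            continue
        d = g.signed_tss_distance(m)
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, cat, d)
    if best is None:
        return RegionAnnotation((chrom, start, end), "distal_intergenic", None, None)
    return RegionAnnotation((chrom, start, end), best[2], best[1], best[3])


def annotate_regions(regions, genes: list[GeneModel], **kw) -> list[RegionAnnotation]:
    """Annotate many regions (accepts MergedRegion objects or tuples)."""
    out = []
    for r in regions:
        tup = r.interval if hasattr(r, "interval") else (r[0], int(r[1]), int(r[2]))
        out.append(annotate_region(tup, genes, **kw))
    return out


def genes_near_peaks(
    regions,
    genes: list[GeneModel],
    margin: int = GENE_MARGIN,
) -> dict[str, list]:
    """Map each gene to the regions whose span intersects the gene span
    extended by ``margin`` bp on both sides (half-open)."""
    out: dict[str, list] = {}
    for g in genes:
        lo, hi = g.span_start - margin, g.span_end + margin
        hits = []
        for r in regions:
            chrom, rs, re_ = r.interval if hasattr(r, "interval") else (r[0], r[1], r[2])
            if chrom == g.chrom and rs < hi and re_ > lo:
                hits.append(r)
        if hits:
            out[g.gene_id] = hits
    return out


def feature_pie(annotations: list[RegionAnnotation]) -> dict[str, float]:
    """Fraction of regions per category (all nine categories, sums to 1)."""
    if not annotations:
        raise ValueError("cannot build a pie from zero annotations")
    n = len(annotations)
    return {c: sum(a.category == c for a in annotations) / n for c in CATEGORIES}


def random_control_peaks(
    regions,
    layout: GenomeLayout,
    seed: int,
) -> list[tuple[str, int, int]]:
    """Random control peaks: same length multiset, uniform genomic placement."""
    lengths = []
    for r in regions:
        chrom, s, e = r.interval if hasattr(r, "interval") else (r[0], r[1], r[2])
        lengths.append(int(e) - int(s))
    rng = substream(seed, "random_control_peaks")
    names = layout.chrom_names
    sizes = layout.sizes()
    out = []
    for L in lengths:
        slots = np.array([max(0, sizes[c] - L + 1) for c in names], dtype=np.int64)
        total = int(slots.sum())
        if total == 0:
            raise ValueError(f"no chromosome can host a {L} bp peak")
        u = int(rng.integers(0, total))
        offsets = np.cumsum(slots)
        ci = int(np.searchsorted(offsets, u, side="right"))
        start = u - (int(offsets[ci - 1]) if ci else 0)
        out.append((names[ci], start, start + L))
    return out
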