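"""Readers and writers for the plain-text interchange formats.

BED6 for tags, islands and hits; BED12 for gene models; FASTA for genome
sequence (via Biopython); bedGraph for binned coverage; TSV for tables.
All interval formats are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeLayout, GeneModel, TagSet
from .islands import BinnedCoverage, Island


# -- chromosome sizes -------------------------------------------------------

def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> GenomeLayout:
    names, lengths = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split("\t")[:2]
        names.append(name)
        lengths.append(int(length))
    return GenomeLayout(tuple(names), tuple(lengths))


# -- FASTA ------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- tags (BED6) ------------------------------------------------------------

def write_tags_bed(tags: TagSet, path) -> None:
    frag = tags.fragments
    with open(path, "w") as fh:
        for chrom, s, e in zip(frag["chrom"], frag["start"], frag["end"]):
            fh.write(f"{chrom}\t{s}\t{e}\t{tags.sample_id}\t0\t.\n")


def read_tags_bed(path, sample_id: str | None = None, group: str = "") -> TagSet:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={0: str},
    )
    sid = sample_id or (str(df["name"].iloc[0]) if len(df) else "sample")
    return TagSet(sid, group, df[["chrom", "start", "end"]])


# -- gene models (BED12) ----------------------------------------------------

def write_genes_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span_start, g.span_end
            sizes = ",".join(str(b - a) for a, b in g.exons)
            starts = ",".join(str(a - s) for a, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{s}\t{e}\t0\t"
                f"{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        chrom, s, e, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = tuple((s + st, s + st + sz) for st, sz in zip(starts, sizes))
        tss, tes = (s, e) if strand == "+" else (e, s)
        genes.append(GeneModel(name, chrom, strand, tss, tes, exons))
    return genes


# -- islands ----------------------------------------------------------------

def write_islands(islands: list[Island], bed_path, tsv_path=None) -> None:
    with open(bed_path, "w") as fh:
        for isl in islands:
            score = min(1000, int(round(10 * isl.score)))
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland\t{score}\t.\n"
            )
    if tsv_path is not None:
        pd.DataFrame(
            [
                {
                    "chrom": i.chrom, "start": i.start, "end": i.end,
                    "tag_count": i.tag_count, "score": i.score,
                    "p": i.p, "fdr": i.fdr,
                }
                for i in islands
            ]
        ).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")


def read_islands_tsv(path) -> list[Island]:
    df = pd.read_csv(path, sep="\t")
    return [
        Island(str(r.chrom), int(r.start), int(r.end), int(r.tag_count),
               float(r.score), float(r.p), float(r.fdr))
        for r in df.itertuples()
    ]


# -- coverage (bedGraph, non-zero bins only) --------------------------------

def write_bedgraph(cov: BinnedCoverage, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov.counts):
            counts = cov.counts[chrom]
            nz = np.flatnonzero(counts)
            clen = cov.chrom_lengths[chrom]
            for i in nz:
                start = int(i) * cov.bin_size
                end = min(start + cov.bin_size, clen)
                fh.write(f"{chrom}\t{start}\t{end}\t{int(counts[i])}\n")


# -- generic tables ---------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
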