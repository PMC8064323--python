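"""Synthetic study generator with machine-readable ground truth.

The generator emulates the data layer of a 3-vs-3 H3K4me3 ChIP-seq study:
a small multi-chromosome genome, strand-aware gene models, per-sample tag
sets whose fragment density is a mixture of uniform Poisson background and
Gaussian promoter-centred enrichment, genome sequence with planted motif
occurrences, and ChIP-qPCR Ct tables with exponential enrichment decay over
the postmortem interval.

Enrichment factors are promoter-density folds: a gene with factor ``f`` in a
group has an expected mean tag density over its TSS +/- 1 kb promoter of
``f`` times the genomic background of that sample, so planted between-group
folds translate directly into the density ratios the differential module
measures.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GeneModel, TagSet

PROMOTER_HALFWIDTH = 1000  # bp; the TSS +/- 1 kb window defining "promoter fold"
FRAGMENT_RANGE = (150, 250)  # in-silico 3' extension length range, bp


def substream(seed: int, label: str) -> np.random.Generator:
    """Per-label RNG derived from a global seed by stable hashing.

    Makes per-sample output independent of the order samples are generated.
    """
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


@dataclass
class SimulationTruth:
    """Ground-truth record of what a simulation planted.

    enriched_genes maps gene_id -> {group: promoter enrichment factor};
    differential_genes are those with a planted between-group fold at or
    above the generator's stated differential fold.
    """

    enriched_genes: dict[str, dict[str, float]]
    differential_genes: set[str]
    planted_motif_sites: list[tuple[str, int, str, str]]
    background_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not set(self.differential_genes) <= set(self.enriched_genes):
            raise ValueError("differential_genes must be a subset of enriched_genes")
        for g, folds in self.enriched_genes.items():
            if any(f <= 0 for f in folds.values()):
                raise ValueError(f"{g}: enrichment factors must be > 0")

    def to_dict(self) -> dict:
        return {
            "enriched_genes": {g: dict(v) for g, v in sorted(self.enriched_genes.items())},
            "differential_genes": sorted(self.differential_genes),
            "planted_motif_sites": [list(t) for t in self.planted_motif_sites],
            "background_rate": self.background_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            enriched_genes={g: dict(v) for g, v in d["enriched_genes"].items()},
            differential_genes=set(d["differential_genes"]),
            planted_motif_sites=[tuple(t) for t in d["planted_motif_sites"]],
            background_rate=float(d["background_rate"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# genome / gene models / sequence


def _make_exons(rng: np.random.Generator, start: int, end: int, max_exons: int) -> tuple:
    length = end - start
    n_exons = int(rng.integers(1, max_exons + 1))
    if n_exons == 1 or length < 2 * n_exons:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * (n_exons - 1), replace=False))
    bounds = np.concatenate(([0], cuts, [length]))
    return tuple(
        (start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
        for i in range(n_exons)
    )


def simulate_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    gene_length_range: tuple[int, int] = (2000, 10000),
    max_exons: int = 5,
    max_tries_per_gene: int = 200,
) -> tuple[GenomeLayout, list[GeneModel], dict[str, str]]:
    """Simulate a genome layout, non-overlapping gene models and sequence.

    Genes are placed uniformly on both strands without span overlap; the
    sequence is uniform-random nucleotides (motif sites are planted
    afterwards with :func:`plant_motif_sites`). Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    layout = GenomeLayout(names, tuple([int(chrom_length)] * n_chroms))

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    genes: list[GeneModel] = []
    width = len(str(max(n_genes, 1)))
    for i in range(n_genes):
        gid = f"g{i + 1:0{width}d}"
        for _ in range(max_tries_per_gene):
            chrom = names[int(rng.integers(0, n_chroms))]
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            if glen >= chrom_length:
                continue
            start = int(rng.integers(0, chrom_length - glen))
            end = start + glen
            if any(start < e and end > s for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(
                GeneModel(gid, chrom, strand, tss, tes, _make_exons(rng, start, end, max_exons))
            )
            break
        else:
            raise RuntimeError(
                f"could not place gene {gid} without overlap after "
                f"{max_tries_per_gene} tries; genome too crowded"
            )

    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        c: bases[rng.integers(0, 4, size=chrom_length)].tobytes().decode()
        for c in names
    }
    return layout, genes, seqs


# ---------------------------------------------------------------------------
# tags


def _promoter_capture(sigma: float, offset: float = 0.0) -> float:
    """Fraction of the Gaussian enrichment mass inside TSS +/- 1 kb."""
    z = lambda x: 0.5 * (1.0 + math.erf(x / (sigma * math.sqrt(2.0))))
    return z(PROMOTER_HALFWIDTH - offset) - z(-PROMOTER_HALFWIDTH - offset)


def simulate_tags(
    layout: GenomeLayout,
    genes: list[GeneModel],
    truth: SimulationTruth,
    n_samples_per_group: int = 3,
    depth: float = 200_000,
    sigma: float = 500.0,
    tss_offset: float = -250.0,
    groups: tuple[str, str] = ("A", "B"),
) -> list[TagSet]:
    """Simulate per-sample tag sets for two groups.

    Fragment midpoints are drawn from a mixture of uniform genomic background
    and, for each enriched gene, a Gaussian (sd ``sigma``) centred
    ``tss_offset`` bp from the TSS in the strand-aware sense (the default
    -250 bp puts the mass on the core promoter just upstream of the TSS)
    whose weight realises the gene's promoter-density fold for the sample's
    group. Fragment lengths are uniform in 150-250 bp; per-sample totals are
    Poisson around ``depth``. Deterministic given ``truth.seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    for g, folds in truth.enriched_genes.items():
        if any(f < 1 for f in folds.values()):
            raise ValueError(f"{g}: enrichment factors must be >= 1")
    gene_by_id = {g.gene_id: g for g in genes}
    unknown = set(truth.enriched_genes) - set(gene_by_id)
    if unknown:
        raise ValueError(f"enriched genes not in gene list: {sorted(unknown)}")

    names = layout.chrom_names
    sizes = layout.sizes()
    offsets = np.concatenate(([0], np.cumsum([sizes[c] for c in names])))
    total_len = layout.total_length
    capture = _promoter_capture(sigma, tss_offset)
    enriched_ids = sorted(truth.enriched_genes)

    samples: list[TagSet] = []
    for group in groups:
        # extra expected tags per background tag unit; see module docstring
        wts = [
            (truth.enriched_genes[gid].get(group, 1.0) - 1.0)
            * 2 * PROMOTER_HALFWIDTH / capture
            for gid in enriched_ids
        ]
        weights = np.array([float(total_len)] + wts)
        probs = weights / weights.sum()
        for rep in range(1, n_samples_per_group + 1):
            sid = f"{group}{rep}"
            rng = substream(truth.seed, sid)
            n = int(rng.poisson(depth))
            comp = rng.choice(len(probs), size=n, p=probs)
            counts = np.bincount(comp, minlength=len(probs))

            chrom_idx = np.empty(n, dtype=np.int64)
            mids = np.empty(n, dtype=np.float64)
            pos = 0
            # background component
            nbg = int(counts[0])
            flat = rng.integers(0, total_len, size=nbg)
            chrom_idx[pos : pos + nbg] = np.searchsorted(offsets, flat, side="right") - 1
            mids[pos : pos + nbg] = flat - offsets[chrom_idx[pos : pos + nbg]]
            pos += nbg
            # enriched components, in stable gene order
            for k, gid in enumerate(enriched_ids):
                cnt = int(counts[k + 1])
                if cnt == 0:
                    continue
                g = gene_by_id[gid]
                ci = names.index(g.chrom)
                centre = g.tss + (tss_offset if g.strand == "+" else -tss_offset)
                m = rng.normal(centre, sigma, size=cnt)
                m = np.clip(np.rint(m), 0, sizes[g.chrom] - 1)
                chrom_idx[pos : pos + cnt] = ci
                mids[pos : pos + cnt] = m
                pos += cnt

            lengths = rng.integers(FRAGMENT_RANGE[0], FRAGMENT_RANGE[1] + 1, size=n)
            starts = np.rint(mids).astype(np.int64) - lengths // 2
            clens = np.array([sizes[names[i]] for i in range(len(names))])[chrom_idx]
            starts = np.clip(starts, 0, clens - lengths)
            frame = pd.DataFrame(
                {
                    "chrom": np.array(names, dtype=object)[chrom_idx],
                    "start": starts,
                    "end": starts + lengths,
                }
            )
            frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort")
            frame = frame.reset_index(drop=True)
            samples.append(TagSet(sid, group, frame))
    return samples


def make_truth(
    genes: list[GeneModel],
    seed: int,
    n_enriched: int,
    base_fold: float = 8.0,
    n_diff_up: int = 0,
    n_diff_down: int = 0,
    diff_fold: float = 3.0,
    spotlight_fold: float | None = None,
    n_weak: int = 0,
    weak_fold: float = 2.4,
    fold_spread: float = 1.0,
    background_rate: float = 0.0,
) -> SimulationTruth:
    """Plant group effects on a random subset of genes.

    Each enriched gene draws a base promoter fold log-uniformly from
    ``[base_fold / fold_spread, base_fold * fold_spread]`` (``fold_spread``
    1 = all equal), emulating the wide dynamic range of real promoter
    strengths. ``n_diff_up`` genes then get a ``diff_fold`` higher fold in
    group B, ``n_diff_down`` in group A; ``n_weak`` genes are borderline-
    enriched in both groups (``weak_fold``, around the island-caller's
    detection limit, so per-sample presence fluctuates as it does for
    marginal peaks); the rest are equally enriched in both groups.
    ``spotlight_fold``, if given, plants one extra modest up-regulated gene
    (e.g. a 2.3-fold promoter increase).
    """
    n_spot = 1 if spotlight_fold is not None else 0
    if n_diff_up + n_diff_down + n_spot + n_weak > n_enriched:
        raise ValueError("more special genes than enriched genes")
    if n_enriched > len(genes):
        raise ValueError("more enriched genes than genes")
    rng = substream(seed, "truth")
    ids = sorted(g.gene_id for g in genes)
    chosen = sorted(rng.choice(len(ids), size=n_enriched, replace=False))
    chosen_ids = [ids[i] for i in chosen]
    enriched: dict[str, dict[str, float]] = {}
    differential: set[str] = set()
    n_dd, n_ds, n_dw = (n_diff_up + n_diff_down,
                        n_diff_up + n_diff_down + n_spot,
                        n_diff_up + n_diff_down + n_spot + n_weak)
    if fold_spread < 1.0:
        raise ValueError("fold_spread must be >= 1")
    lo, hi = math.log(base_fold / fold_spread), math.log(base_fold * fold_spread)
    for j, gid in enumerate(chosen_ids):
        f = math.exp(rng.uniform(lo, hi))
        if j < n_diff_up:
            enriched[gid] = {"A": f, "B": f * diff_fold}
            differential.add(gid)
        elif j < n_dd:
            enriched[gid] = {"A": f * diff_fold, "B": f}
            differential.add(gid)
        elif n_spot and j == n_dd:
            enriched[gid] = {"A": f, "B": f * spotlight_fold}
        elif j < n_dw:
            enriched[gid] = {"A": weak_fold, "B": weak_fold}
        else:
            enriched[gid] = {"A": f, "B": f}
    return SimulationTruth(enriched, differential, [], background_rate, seed)


def spotlight_gene(truth: SimulationTruth, diff_fold: float) -> str | None:
    """The single planted gene whose fold differs from 1 and from diff_fold."""
    for gid in sorted(truth.enriched_genes):
        f = truth.enriched_genes[gid]
        r = f["B"] / f["A"]
        if not math.isclose(r, 1.0) and not math.isclose(r, diff_fold) \
                and not math.isclose(r, 1.0 / diff_fold):
            return gid
    return None


# ---------------------------------------------------------------------------
# motif planting


def plant_motif_sites(
    seqs: dict[str, str],
    intervals: list[tuple[str, int, int]],
    consensus: str,
    motif_id: str,
    mean_sites: float,
    seed: int,
) -> list[tuple[str, int, str, str]]:
    """Plant non-overlapping consensus occurrences inside intervals.

    The number of sites per interval is Poisson(``mean_sites``); each site is
    written on a random strand (reverse-complement on '-'). Mutates ``seqs``
    in place and returns the planted (chrom, pos, motif_id, strand) records.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rng = substream(seed, f"plant:{motif_id}")
    L = len(consensus)
    planted: list[tuple[str, int, str, str]] = []
    buffers = {c: bytearray(s, "ascii") for c, s in seqs.items()}
    for chrom, start, end in intervals:
        if chrom not in buffers:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo, hi = max(0, start), min(len(buffers[chrom]), end)
        if hi - lo < L:
            continue
        n = int(rng.poisson(mean_sites))
        taken: list[tuple[int, int]] = []
        for _ in range(n):
            for _try in range(50):
                pos = int(rng.integers(lo, hi - L + 1))
                if all(pos + L <= a or pos >= b for a, b in taken):
                    break
            else:
                continue
            taken.append((pos, pos + L))
            strand = "+" if rng.random() < 0.5 else "-"
            site = consensus if strand == "+" else consensus.translate(comp)[::-1]
            buffers[chrom][pos : pos + L] = site.encode()
            planted.append((chrom, pos, motif_id, strand))
    for c in seqs:
        seqs[c] = buffers[c].decode()
    planted.sort()
    return planted


# ---------------------------------------------------------------------------
# ChIP-qPCR


def simulate_qpcr(
    timepoints: tuple[float, ...] = (0, 6, 24, 48, 72, 96),
    replicates: int = 3,
    seed: int = 0,
    halflife: dict[str, float] | None = None,
    baseline_fold: dict[str, float] | None = None,
    positive_targets: tuple[str, ...] = ("ACTB", "GAPDH"),
    negative_target: str = "Untr6",
    negative_percent_input: float = 0.05,
    ct_input_mean: float = 20.0,
    ct_noise_sd: float = 0.15,
    input_fraction: float = 1.0,
) -> pd.DataFrame:
    """Simulate a ChIP-qPCR Ct table with planted postmortem decay.

    Positive-target enrichment (fold over the negative-control gene-desert
    region) decays exponentially with the postmortem interval with a
    per-antibody half-life (``math.inf`` = no decay); the negative control is
    flat. Gaussian noise is added on the Ct scale.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if halflife is None:
        halflife = {"H3K4me3": 60.0, "H3K27Ac": 45.0, "RNAPol": 18.0}
    if baseline_fold is None:
        baseline_fold = {"H3K4me3": 200.0, "H3K27Ac": 80.0, "RNAPol": 20.0}
    rng = substream(seed, "qpcr")
    dilution = math.log2(1.0 / input_fraction)
    rows = []
    for antibody in sorted(halflife):
        hl = halflife[antibody]
        for target in (*positive_targets, negative_target):
            for t in timepoints:
                decay = 1.0 if math.isinf(hl) else 2.0 ** (-t / hl)
                if target == negative_target:
                    pi = negative_percent_input
                else:
                    pi = negative_percent_input * baseline_fold[antibody] * decay
                for rep in range(1, replicates + 1):
                    ct_input = ct_input_mean + rng.normal(0.0, ct_noise_sd)
                    ct_ip = (
                        ct_input - dilution - math.log2(pi / 100.0)
                        + rng.normal(0.0, ct_noise_sd)
                    )
                    rows.append(
                        {
                            "antibody": antibody,
                            "target": target,
                            "timepoint_h": float(t),
                            "replicate": rep,
                            "ct_ip": round(float(ct_ip), 4),
                            "ct_input": round(float(ct_input), 4),
                        }
                    )
    return pd.DataFrame(rows)
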