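"""PWM motif scanning of interval sequences.

Position frequency matrices (JASPAR plain-text format) are converted to
log-odds weights with one pseudocount mass distributed by the background:
``lo[b][i] = log2((counts[b][i] + bg[b]) / (colsum[i] + 1)) - log2(bg[b])``.
Window scores are min-max normalized to [0, 1] (1 = the consensus), both
strands are scanned, and windows containing N are skipped. The headline
statistic is the average number of binding sites per interval sequence
after adding 200 bp flanks to each interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
DEFAULT_CUTOFF = 0.85
DEFAULT_FLANK = 200

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Synthetic demonstration motif library (JASPAR plain-text PFM format).
# These are invented matrices for planted-truth simulations, loosely shaped
# like a GC-box, a composite AT-rich box and a palindromic CRE-like element;
# they are not measured binding profiles.
BUILTIN_MOTIFS_PFM = """\
>SYN001 GCbox-syn
A  [  2  1  0  0  1  0  0  1  0  2 ]
C  [  1  0  2  0  0  2  0  0  2  1 ]
G  [ 15 17 16 18 17 16 18 17 16 15 ]
T  [  0  0  0  0  0  0  0  0  0  0 ]
>SYN002 ATbox-syn
A  [ 16  2 18 17  0  1 17 16 ]
C  [  1  0  0  0  1 16  0  1 ]
G  [  1  0  0  1  1  1  0  1 ]
T  [  0 16  0  0 16  0  1  0 ]
>SYN003 CRE-syn
A  [  1  0 16  0  0  1  0  1 ]
C  [  1 16  0 16  0  0  1  0 ]
G  [ 16  0  1  0 16  0  0  1 ]
T  [  0  2  1  2  2 17 17 16 ]
"""


class PFMParseError(ValueError):
    pass


@dataclass
class PWMotif:
    """A position weight model with log-odds weights derived from counts."""

    motif_id: str
    factor_name: str = ""
    classification: str = ""
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 0)))
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (A,C,G,T rows)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0)
        p = self.pseudocount
        bg = self.background[:, None]
        freq = (self.counts + p * bg) / (colsum + p)
        return np.log2(freq) - np.log2(bg)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PWMotif":
        return PWMotif(
            self.motif_id,
            self.factor_name,
            self.classification,
            self.counts[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHitSummary:
    motif_id: str
    factor_name: str
    classification: str
    n_intervals_scanned: int
    total_sites: int

    @property
    def avg_sites_per_interval(self) -> float:
        if self.n_intervals_scanned <= 0:
            raise ValueError("average undefined for zero intervals")
        return self.total_sites / self.n_intervals_scanned


# ---------------------------------------------------------------------------
# parsing


def _parse_matrix_line(line: str, row: int) -> list[float]:
    body = line.strip()
    if body[:1].upper() in BASES and (body[1:2].isspace() or body[1:2] == "["):
        body = body[1:]
    body = body.replace("[", " ").replace("]", " ")
    try:
        vals = [float(x) for x in body.split()]
    except ValueError as exc:
        raise PFMParseError(f"row {row + 1}: cannot parse matrix line {line!r}") from exc
    return vals


def load_pfm(text: str) -> PWMotif:
    """Parse a single JASPAR-format PFM (with or without base-row labels)."""
    motifs = load_pfm_library(text)
    if len(motifs) != 1:
        raise PFMParseError(f"expected exactly one motif, found {len(motifs)}")
    return motifs[0]


def load_pfm_library(text: str) -> list[PWMotif]:
    """Parse one or more JASPAR-format PFMs from plain text.

    Headers look like ``>MA0079.5 SP1`` (an optional third token is kept as
    the classification tag); the matrix is four rows of equal length.
    """
    motifs: list[PWMotif] = []
    header: tuple[str, str, str] | None = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if not rows and header is None:
            return
        if len(rows) != 4:
            raise PFMParseError(f"expected 4 matrix rows, found {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise PFMParseError(
                f"ragged matrix: row lengths {sorted(len(r) for r in rows)}"
            )
        counts = np.array(rows, dtype=float)
        if (counts < 0).any():
            b, i = np.argwhere(counts < 0)[0]
            raise PFMParseError(f"negative count at row {b + 1}, column {i + 1}")
        mid, name, cls = header if header else (f"motif{len(motifs) + 1}", "", "")
        motifs.append(PWMotif(mid, name, cls, counts))
        header, rows = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            toks = line[1:].split()
            header = (
                toks[0] if toks else "",
                toks[1] if len(toks) > 1 else "",
                toks[2] if len(toks) > 2 else "",
            )
        else:
            rows.append(_parse_matrix_line(line, len(rows)))
    flush()
    if not motifs:
        raise PFMParseError("no motif found")
    return motifs


# ---------------------------------------------------------------------------
# scanning

_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _strand_scores(idx: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = lo.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (win < 4).all(axis=1)
    lo5 = np.vstack([lo, np.zeros((1, L))])  # N row, masked out by `valid`
    scores = lo5[win, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_interval(seq: str, motif: PWMotif, cutoff: float = DEFAULT_CUTOFF):
    """Scan a sequence on both strands; hits are (offset, strand, score).

    ``score`` is the min-max normalized log-odds score in [0, 1]; hits at or
    above ``cutoff`` are reported, overlapping hits included. Offsets refer
    to the forward sequence for both strands. Windows containing N are
    skipped; sequences shorter than the motif yield no hits.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    L = motif.length
    if len(seq) < L:
        return []
    lo = motif.log_odds
    smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
    span = smax - smin
    idx = _encode(seq)
    hits = []
    for strand, mat in (("+", lo), ("-", motif.reverse_complement().log_odds)):
        scores, valid = _strand_scores(idx, mat)
        norm = np.ones_like(scores) if span == 0 else (scores - smin) / span
        for off in np.flatnonzero(valid & (norm >= cutoff)):
            hits.append((int(off), strand, float(norm[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def motif_frequency_table(
    intervals,
    genome: dict[str, str],
    motifs: list[PWMotif],
    flank: int = DEFAULT_FLANK,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[MotifHitSummary]:
    """Average binding sites per flanked interval, ranked descending.

    ``intervals`` are MergedRegions or (chrom, start, end) tuples; flanks
    are clipped at chromosome ends. Raises on zero intervals (the average
    is undefined) and on a chromosome absent from the genome.
    """
    ivs = []
    for r in intervals:
        chrom, s, e = r.interval if hasattr(r, "interval") else (r[0], r[1], r[2])
        ivs.append((str(chrom), int(s), int(e)))
    if not ivs:
        raise ValueError("average sites per interval undefined for zero intervals")
    seqs = []
    for chrom, s, e in ivs:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        ref = genome[chrom]
        seqs.append(str(ref[max(0, s - flank) : min(len(ref), e + flank)]))
    summaries = []
    for m in motifs:
        total = sum(len(scan_interval(s, m, cutoff)) for s in seqs)
        summaries.append(
            MotifHitSummary(m.motif_id, m.factor_name, m.classification, len(ivs), total)
        )
    summaries.sort(key=lambda s: (-s.avg_sites_per_interval, s.motif_id))
    return summaries


def summary_frame(summaries: list[MotifHitSummary]) -> pd.DataFrame:
    """Table mirroring the usual motif-frequency report columns."""
    return pd.DataFrame(
        [
            {
                "Matrix": s.motif_id,
                "Factor": s.factor_name,
                "Classification": s.classification,
                "n_intervals": s.n_intervals_scanned,
                "total_sites": s.total_sites,
                "avg_sites_per_interval": s.avg_sites_per_interval,
            }
            for s in summaries
        ]
    )


def scan_hits_bed(
    intervals,
    genome: dict[str, str],
    motifs: list[PWMotif],
    flank: int = DEFAULT_FLANK,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Genome-coordinate hit table (BED6-shaped) across flanked intervals."""
    rows = []
    for r in intervals:
        chrom, s, e = r.interval if hasattr(r, "interval") else (r[0], r[1], r[2])
        ref = genome[chrom]
        lo = max(0, int(s) - flank)
        seq = str(ref[lo : min(len(ref), int(e) + flank)])
        for m in motifs:
            for off, strand, score in scan_interval(seq, m, cutoff):
                rows.append(
                    {
                        "chrom": chrom,
                        "start": lo + off,
                        "end": lo + off + m.length,
                        "name": m.motif_id,
                        "score": int(round(1000 * score)),
                        "strand": strand,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
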