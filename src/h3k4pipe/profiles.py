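"""Average plots, heatmap matrices and clustering around genomic anchors.

Rows are anchors (genes, merged regions or promoters), columns are fixed-
width bins of fragment-midpoint counts, oriented so upstream is always on
the left. Gene bodies are length-scaled to a fixed meta-length before
flanks are added (meta-gene convention), merged regions are anchored at
their midpoint, promoters at the TSS. Heatmap rows are clustered with
k-means (default 5 clusters) on row-normalized profiles; cluster labels are
reordered by descending mean signal so C1..C5 are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .genome import GeneModel, TagSet
from .intervals import MergedRegion

DEFAULT_BIN = 32
META_LENGTH = 2000  # pseudo-bp a gene body is rescaled to

_FLANKS = {"gene_body": 2000, "merged_region": 5000, "promoter": 1500}


@dataclass
class ProfileMatrix:
    anchor_set: str
    flank: int
    bin_size: int
    matrix: np.ndarray
    row_ids: list[str]
    cluster_labels: np.ndarray | None = None


def _pooled_midpoints(tags) -> dict[str, np.ndarray]:
    if isinstance(tags, TagSet):
        tags = [tags]
    pooled: dict[str, list[np.ndarray]] = {}
    for ts in tags:
        for chrom, mids in ts.midpoints().items():
            pooled.setdefault(chrom, []).append(mids)
    return {c: np.sort(np.concatenate(v)) for c, v in pooled.items()}


def _window_row(mids: np.ndarray | None, left: int, n_bins: int, bin_size: int) -> np.ndarray:
    if mids is None:
        return np.zeros(n_bins)
    edges = left + bin_size * np.arange(n_bins + 1)
    return np.diff(np.searchsorted(mids, edges, side="left")).astype(float)


def build_profile(
    tags,
    anchors,
    anchor_set: str,
    flank: int | None = None,
    bin_size: int = DEFAULT_BIN,
    meta_length: int = META_LENGTH,
) -> ProfileMatrix:
    """Build the anchors x bins tag-count matrix for one anchor set.

    ``tags`` may be a TagSet or a list of TagSets (pooled). ``anchors`` are
    GeneModels for ``gene_body``/``promoter`` and MergedRegions (or
    (chrom, start, end) tuples) for ``merged_region``.
    """
    if anchor_set not in _FLANKS:
        raise ValueError(f"anchor_set must be one of {sorted(_FLANKS)}")
    if not len(anchors):
        raise ValueError("anchors must be non-empty")
    if flank is None:
        flank = _FLANKS[anchor_set]
    if flank % bin_size:  # snap to the bin grid
        flank = -(-flank // bin_size) * bin_size
    if meta_length % bin_size:
        meta_length = -(-meta_length // bin_size) * bin_size
    mids = _pooled_midpoints(tags)
    nf = flank // bin_size

    rows, ids = [], []
    if anchor_set == "promoter":
        for g in anchors:
            row = _window_row(mids.get(g.chrom), g.tss - flank, 2 * nf, bin_size)
            rows.append(row[::-1] if g.strand == "-" else row)
            ids.append(g.gene_id)
    elif anchor_set == "merged_region":
        for r in anchors:
            chrom, s, e = r.interval if hasattr(r, "interval") else (r[0], r[1], r[2])
            mid = (int(s) + int(e)) // 2
            rows.append(_window_row(mids.get(chrom), mid - flank, 2 * nf, bin_size))
            ids.append(f"{chrom}:{s}-{e}")
    else:  # gene_body: scaled body flanked by unscaled margins
        nb = meta_length // bin_size
        for g in anchors:
            arr = mids.get(g.chrom)
            s, e = g.span_start, g.span_end
            up = _window_row(arr, s - flank, nf, bin_size)
            dn = _window_row(arr, e, nf, bin_size)
            body = np.zeros(nb)
            if arr is not None:
                inside = arr[(arr >= s) & (arr < e)]
                if inside.size:
                    idx = ((inside - s) * nb) // (e - s)
                    body = np.bincount(idx.astype(int), minlength=nb).astype(float)
            row = np.concatenate([up, body, dn])
            rows.append(row[::-1] if g.strand == "-" else row)
            ids.append(g.gene_id)
    return ProfileMatrix(anchor_set, flank, bin_size, np.vstack(rows), ids)


def cluster_profiles(matrix: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """K-means cluster labels (1..k) on row-normalized profiles.

    Labels are renumbered by descending mean raw row signal, so cluster 1 is
    always the strongest; deterministic given ``seed``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k == 1:
        return np.ones(len(matrix), dtype=int)
    sums = matrix.sum(axis=1, keepdims=True)
    norm = np.divide(matrix, sums, out=np.zeros_like(matrix), where=sums > 0)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw = km.fit_predict(norm)
    order = np.argsort(
        [-matrix[raw == c].sum(axis=1).mean() if (raw == c).any() else np.inf
         for c in range(k)],
        kind="mergesort",
    )
    remap = {int(c): rank + 1 for rank, c in enumerate(order)}
    return np.array([remap[int(c)] for c in raw], dtype=int)


def average_plot(matrix: np.ndarray) -> np.ndarray:
    """Per-bin mean over all rows (the histogram in an average plot)."""
    matrix = np.asarray(matrix, dtype=float)
    return matrix.mean(axis=0)


def group_scatter_qc(region_means_a, region_means_b) -> tuple[float, float]:
    """Pearson r and OLS slope (with intercept) of group B means on group A."""
    a = np.asarray(region_means_a, dtype=float)
    b = np.asarray(region_means_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired points")
    fit = stats.linregress(a, b)
    return float(fit.rvalue), float(fit.slope)


def save_average_plot(vec: np.ndarray, path, title: str = "", bin_size: int = DEFAULT_BIN):
    """Optional PNG rendering of an average plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = (np.arange(len(vec)) - len(vec) / 2) * bin_size
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(x, vec, lw=1.2)
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("mean tag count / bin")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
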