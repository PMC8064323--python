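"""Per-gene signal quantification and fold-change differential calling.

Signal is the length-corrected tag density (fragments per kb, counted by
midpoint) in either the promoter window (TSS +/- 1 kb, strand-aware) or the
gene body (TSS to TES). Group means are taken on the density scale; the
between-group ratio uses a pseudocount to guard zero densities, and the
p-value is a two-sided Welch t-test on log2(density + pseudocount). A
target passes the differential filter when the ratio is at least 1.5-fold
in either direction and p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, TagSet
from .intervals import MergedRegion

log = logging.getLogger(__name__)

FC_CUTOFF = 1.5
ALPHA = 0.05
PSEUDOCOUNT = 0.5  # tags/kb
PROMOTER_HALF = 1000


def _windows(genes: list[GeneModel], window: str, promoter_half: int):
    if window == "promoter":
        for g in genes:
            s, e = g.promoter(promoter_half)
            yield g.gene_id, g.chrom, max(0, s), e
    elif window == "gene_body":
        for g in genes:
            yield g.gene_id, g.chrom, g.span_start, g.span_end
    else:
        raise ValueError(f"window must be 'promoter' or 'gene_body', got {window!r}")


def quantify_signal(
    tags: TagSet,
    genes: list[GeneModel],
    window: str = "promoter",
    promoter_half: int = PROMOTER_HALF,
) -> pd.DataFrame:
    """Tag density per kb for each gene's quantification window.

    Returns a DataFrame with columns target_id, sample_id, raw_count,
    window_bp, tag_density.
    """
    mids = tags.midpoints()
    rows = []
    for gid, chrom, s, e in _windows(genes, window, promoter_half):
        if e <= s:
            raise ValueError(f"{gid}: zero-length quantification window")
        arr = mids.get(chrom)
        n = 0 if arr is None else int(
            np.searchsorted(arr, e, "left") - np.searchsorted(arr, s, "left")
        )
        rows.append(
            {
                "target_id": gid,
                "sample_id": tags.sample_id,
                "raw_count": n,
                "window_bp": e - s,
                "tag_density": n / ((e - s) / 1000.0),
            }
        )
    return pd.DataFrame(rows)


def density_matrix(
    samples: list[TagSet],
    genes: list[GeneModel],
    window: str = "promoter",
    promoter_half: int = PROMOTER_HALF,
) -> pd.DataFrame:
    """Targets x samples matrix of tag densities (tags/kb)."""
    cols = {}
    for ts in samples:
        q = quantify_signal(ts, genes, window, promoter_half)
        cols[ts.sample_id] = q.set_index("target_id")["tag_density"]
    return pd.DataFrame(cols)


def differential_call(
    densities: pd.DataFrame,
    groups: dict[str, str],
    fc_cutoff: float = FC_CUTOFF,
    alpha: float = ALPHA,
    pseudo: float = PSEUDOCOUNT,
    presence: pd.DataFrame | None = None,
    group_a: str = "A",
    group_b: str = "B",
    test: str = "welch",
) -> pd.DataFrame:
    """Differential activity records from a targets x samples density matrix.

    ratio = (mean_B + pseudo) / (mean_A + pseudo) on the density scale;
    p from a two-sided t-test on log2(density + pseudo) (``test``: "welch"
    for unequal variances, "pooled" for the classic equal-variance t); a BH
    column is reported for transparency but the pass filter uses the raw p,
    as is conventional for this fold-change screen.
    """
    if test not in ("welch", "pooled"):
        raise ValueError("test must be 'welch' or 'pooled'")
    a_cols = sorted(s for s in densities.columns if groups[s] == group_a)
    b_cols = sorted(s for s in densities.columns if groups[s] == group_b)
    if not a_cols or not b_cols:
        raise ValueError("both groups must have at least one sample")
    A = densities[a_cols].to_numpy(dtype=float)
    B = densities[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ratio = (mean_b + pseudo) / (mean_a + pseudo)
    log2fc = np.log2(ratio)

    if len(a_cols) < 2 or len(b_cols) < 2:
        log.warning("a group has < 2 samples; p-values undefined, filter uses fold only")
        p = np.full(len(densities), np.nan)
    else:
        import warnings

        with warnings.catch_warnings():
            # constant rows give 0/0 t statistics; handled as p = 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(
                np.log2(A + pseudo), np.log2(B + pseudo), axis=1,
                equal_var=(test == "pooled"),
            ).pvalue
        p = np.asarray(p, dtype=float)
        # identical groups give 0/0 -> nan; that is "no evidence", p = 1
        p = np.where(np.isnan(p), 1.0, p)

    fc_pass = (ratio >= fc_cutoff) | (ratio <= 1.0 / fc_cutoff)
    if np.isnan(p).all():
        passes = fc_pass
    else:
        passes = fc_pass & (p < alpha)

    bh = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        bh[ok] = _bh(p[ok])

    if presence is not None:
        pres = presence.reindex(densities.index)
        present_a = pres[[c for c in a_cols if c in pres.columns]].sum(axis=1) > 0
        present_b = pres[[c for c in b_cols if c in pres.columns]].sum(axis=1) > 0
    else:
        present_a = (A > 0).any(axis=1)
        present_b = (B > 0).any(axis=1)

    out = pd.DataFrame(
        {
            "target_id": densities.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "ratio": ratio,
            "log2fc": log2fc,
            "p": p,
            "bh_q": bh,
            "present_A": np.asarray(present_a, dtype=bool),
            "present_B": np.asarray(present_b, dtype=bool),
            "passes_filter": passes,
        }
    )
    out["_abs"] = out["log2fc"].abs()
    out = out.sort_values(["p", "_abs"], ascending=[True, False], kind="mergesort",
                          na_position="last")
    return out.drop(columns="_abs").reset_index(drop=True)


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def presence_matrix(merged: list[MergedRegion]) -> pd.DataFrame:
    """Binary region x sample matrix from merged-region membership."""
    samples = sorted({s for r in merged for s in r.present_in})
    data = {
        r.region_id: [int(r.present_in.get(s, False)) for s in samples] for r in merged
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=samples).astype(int)
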