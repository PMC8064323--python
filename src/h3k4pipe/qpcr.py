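"""ChIP-qPCR enrichment and postmortem-stability statistics.

Enrichment is expressed as percent input, ``100 * 2^((ct_input - log2(1 /
input_fraction)) - ct_ip)``, and as fold over the matched negative-control
(gene-desert) region within the same antibody / timepoint / replicate.
Stability over the postmortem interval is tested with a one-way fixed-
effects ANOVA across timepoints followed by Bonferroni-adjusted pairwise
t-tests, and summarized by the OLS slope of log2 fold-enrichment on time.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


def percent_input(ct_ip, ct_input, input_fraction: float = 1.0):
    """Percent-input enrichment with dilution adjustment."""
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    adj = np.asarray(ct_input, dtype=float) - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adj - np.asarray(ct_ip, dtype=float))


def enrichment_table(
    records: pd.DataFrame,
    input_fraction: float = 1.0,
    negative_target: str = "Untr6",
) -> pd.DataFrame:
    """Per-record percent_input and fold over the matched negative control.

    Records are matched on (antibody, timepoint_h, replicate); a missing
    matched negative record is an error. The negative region against itself
    is exactly 1.
    """
    df = records.copy()
    df["percent_input"] = percent_input(df["ct_ip"], df["ct_input"], input_fraction)
    neg = df[df["target"] == negative_target]
    if neg.empty:
        raise ValueError(f"no records for negative target {negative_target!r}")
    key = ["antibody", "timepoint_h", "replicate"]
    neg_pi = neg.set_index(key)["percent_input"]
    if neg_pi.index.has_duplicates:
        raise ValueError("duplicate negative-control records for a matching key")
    idx = pd.MultiIndex.from_frame(df[key])
    matched = neg_pi.reindex(idx).to_numpy()
    if np.isnan(matched).any():
        bad = df.loc[np.isnan(matched), key].iloc[0].tolist()
        raise ValueError(f"missing matched negative record for {bad}")
    df["fold_over_negative"] = df["percent_input"].to_numpy() / matched
    return df


def stability_anova(
    values: pd.DataFrame,
    value_col: str = "fold_over_negative",
    group_col: str = "timepoint_h",
    alpha: float = ALPHA,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across timepoints plus Bonferroni pairwise t-tests.

    Returns (F, p, pairwise table); the pairwise table has one row per
    timepoint pair with raw and Bonferroni-adjusted p-values and a
    significance flag at ``alpha``.
    """
    levels = sorted(values[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 timepoints")
    arrays = [values.loc[values[group_col] == g, value_col].to_numpy(float) for g in levels]
    for g, a in zip(levels, arrays):
        if len(a) < 2:
            raise ValueError(f"timepoint {g}: need >= 2 replicates")

    grand = np.concatenate(arrays)
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = len(arrays) - 1, len(grand) - len(arrays)
    if ss_within == 0 and ss_between == 0:
        f_stat, p_val = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_val = math.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_val = float(stats.f.sf(f_stat, df_b, df_w))

    pairs = list(itertools.combinations(range(len(levels)), 2))
    rows = []
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
        else:
            import warnings

            with warnings.catch_warnings():
                # a zero-variance group alongside a varying one is fine here
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=True)
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append(
            {
                "group_1": levels[i],
                "group_2": levels[j],
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return float(f_stat), float(p_val), pd.DataFrame(rows)


def decay_slope(
    results: pd.DataFrame,
    value_col: str = "fold_over_negative",
    time_col: str = "timepoint_h",
    by: str = "antibody",
) -> pd.DataFrame:
    """OLS slope of log2 enrichment on postmortem hours, per antibody.

    A more negative slope means faster decay; exact halving every 24 h gives
    slope -1/24 per hour. Reported with the standard error of the slope.
    """
    rows = []
    for key, sub in results.groupby(by, sort=True):
        vals = sub[value_col].to_numpy(float)
        if (vals <= 0).any():
            raise ValueError(f"{key}: enrichment must be positive for the log slope")
        fit = stats.linregress(sub[time_col].to_numpy(float), np.log2(vals))
        rows.append(
            {
                by: key,
                "slope_per_h": float(fit.slope),
                "stderr": float(fit.stderr),
                "intercept_log2": float(fit.intercept),
            }
        )
    return pd.DataFrame(rows)
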