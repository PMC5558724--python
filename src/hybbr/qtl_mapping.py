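"""QTL mapping from posterior class probabilities.

The mapping signal for variant i is P(i,4): the posterior probability of
membership in the mixture class with the largest variance (0.01 x
sigma_g2). The reporting threshold is set so that the number of variants
above it matches the posterior-expected count of largest-class variants,
N4 = round(Pr_4 * m).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bayesr import PosteriorSummary

logger = logging.getLogger(__name__)


def top_class_probability(summary: PosteriorSummary) -> pd.DataFrame:
    """Per-variant P(i,4) with genomic coordinates, Manhattan-ready."""
    m = summary.P.shape[0]
    return pd.DataFrame({
        "variant_id": (summary.variant_ids if summary.variant_ids is not None
                       else np.arange(m).astype(str)),
        "chrom": (summary.chrom if summary.chrom is not None
                  else np.array(["1"] * m)),
        "pos_bp": (summary.pos_bp if summary.pos_bp is not None
                   else np.arange(1, m + 1)),
        "q4": summary.P[:, 3],
        "g_mean": summary.g_mean,
    })


def qtl_threshold(q4: np.ndarray, pr_mean: np.ndarray, m: int | None = None):
    """Probability threshold admitting ~round(Pr_4 * m) variants.

    Returns (threshold, N4). With an expected count of zero the threshold
    is max(q4) and the report is empty apart from exact ties at the top.
    """
    q4 = np.asarray(q4, float)
    if m is None:
        m = q4.shape[0]
    n4 = int(round(float(pr_mean[3]) * m))
    if n4 <= 0:
        logger.info("expected largest-class count is zero; empty QTL report")
        return float(np.max(q4)), 0
    n4 = min(n4, q4.shape[0])
    threshold = float(np.sort(q4)[::-1][n4 - 1])
    return threshold, n4


def top_variants_report(table: pd.DataFrame, threshold: float,
                        n4: int | None = None) -> pd.DataFrame:
    """Variants with q4 >= threshold, sorted by q4 desc then (chrom, pos).

    When ``n4`` is 0 an empty table (header only) is returned.
    """
    if n4 == 0:
        return table.iloc[0:0]
    hits = table[table["q4"] >= threshold].copy()
    hits = hits.sort_values(["q4", "chrom", "pos_bp"],
                            ascending=[False, True, True])
    return hits.reset_index(drop=True)


def window_summary(table: pd.DataFrame, window_kb: float) -> pd.DataFrame:
    """Optional aggregation: max q4 and summed |g_mean| per genomic window."""
    t = table.copy()
    t["window"] = (t["pos_bp"] // int(window_kb * 1000)).astype(int)
    agg = (t.groupby(["chrom", "window"])
           .agg(q4_max=("q4", "max"), n_variants=("q4", "size"),
                abs_g_sum=("g_mean", lambda s: float(np.abs(s).sum())),
                pos_start=("pos_bp", "min"), pos_end=("pos_bp", "max"))
           .reset_index())
    return agg.sort_values(["chrom", "window"]).reset_index(drop=True)
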