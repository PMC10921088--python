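"""Pairwise model comparison: pixelwise McNemar tests with FDR control.

For each pair of segmentation models, per-pixel correctness against the
ground truth is reduced to the two discordant counts of the paired 2x2
table: b (A correct, B wrong) and c (B correct, A wrong).  McNemar's
statistic (b-c)^2/(b+c) is referred to the chi-squared distribution with
one degree of freedom.  The resulting p-values across all C(k,2) pairs
are ranked by the Benjamini-Hochberg step-up procedure, whose rank-i
critical value is (i/m)*alpha; all pairs at or below the largest rank
whose p-value clears its critical value are declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DiscordanceCounts",
    "McNemarResult",
    "discordance",
    "mcnemar_test",
    "bh_procedure",
    "compare_models",
]


@dataclass
class DiscordanceCounts:
    b: int  # pixels where A is correct and B is wrong
    c: int  # pixels where B is correct and A is wrong
    n_pixels: int

    def __post_init__(self):
        if self.b < 0 or self.c < 0:
            raise ValueError("discordant counts must be nonnegative")
        if self.b + self.c > self.n_pixels:
            raise ValueError("b + c cannot exceed the number of pixels compared")


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    no_discordance: bool = False


def discordance(pred_a: np.ndarray, pred_b: np.ndarray, gt: np.ndarray) -> DiscordanceCounts:
    """Discordant pixel counts for two binarized predictions against ground truth."""
    pred_a = np.asarray(pred_a).astype(bool)
    pred_b = np.asarray(pred_b).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if not (pred_a.shape == pred_b.shape == gt.shape):
        raise ValueError(
            f"shape mismatch: A {pred_a.shape}, B {pred_b.shape}, gt {gt.shape}"
        )
    ok_a = pred_a == gt
    ok_b = pred_b == gt
    return DiscordanceCounts(
        b=int(np.sum(ok_a & ~ok_b)),
        c=int(np.sum(~ok_a & ok_b)),
        n_pixels=int(gt.size),
    )


def mcnemar_test(counts: DiscordanceCounts, correction: bool = False) -> McNemarResult:
    """McNemar chi-squared test (1 df) on the discordant counts.

    ``correction`` applies the Edwards continuity correction; the default
    is the plain statistic, appropriate for the huge pixel counts this is
    used on.  With no discordant pixels the test is undefined and p=1 is
    reported with a flag.
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, no_discordance=True)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c) if abs(b - c) > 1 else 0.0
    else:
        stat = (b - c) ** 2 / (b + c)
    return McNemarResult(statistic=float(stat), p_value=float(sps.chi2.sf(stat, df=1)))


def bh_procedure(p_values, alpha: float = 0.05, labels=None) -> pd.DataFrame:
    """Benjamini-Hochberg step-up procedure.

    Returns one row per test, sorted by ascending p-value, with columns
    (pair, p_value, rank, critical_value, significant).  The critical
    value at rank i is (i/m)*alpha; every test ranked at or below the
    largest i with p_(i) <= (i/m)*alpha is significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a one-dimensional collection of at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    m = p.size
    if labels is None:
        labels = [f"test_{i}" for i in range(m)]
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    criticals = ranks / m * alpha
    sorted_p = p[order]
    passing = np.nonzero(sorted_p <= criticals)[0]
    cutoff = passing.max() + 1 if passing.size else 0  # largest qualifying rank
    return pd.DataFrame(
        {
            "pair": [labels[i] for i in order],
            "p_value": sorted_p,
            "rank": ranks,
            "critical_value": criticals,
            "significant": ranks <= cutoff,
        }
    )


def compare_models(
    predictions: dict[str, np.ndarray],
    gt: np.ndarray,
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Full pairwise comparison table for binarized predictions of k models.

    ``predictions`` maps model name to a {0,1} mask array (any shape, all
    identical); pixels are pooled into one 2x2 table per pair.  Returns the
    BH-ranked table with the discordant counts and raw statistics attached.
    """
    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    rows = {}
    for a, b in combinations(names, 2):
        d = discordance(predictions[a], predictions[b], gt)
        r = mcnemar_test(d, correction=correction)
        rows[f"({a}, {b})"] = (d, r)
    labels = list(rows)
    table = bh_procedure([rows[k][1].p_value for k in labels], alpha=alpha, labels=labels)
    table["b"] = [rows[k][0].b for k in table["pair"]]
    table["c"] = [rows[k][0].c for k in table["pair"]]
    table["statistic"] = [rows[k][1].statistic for k in table["pair"]]
    return table
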