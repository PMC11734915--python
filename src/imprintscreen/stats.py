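"""Expression-level statistics: TPM, Welch's t, BH FDR, fold changes, DEG calls.

DEG criteria: absolute log2 fold change strictly greater than 1 and
BH-adjusted FDR strictly below 0.05.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegConfig",
    "compute_tpm",
    "welch_t",
    "bh_fdr",
    "fold_change",
    "round_fold",
    "deg_call",
    "expression_stats_table",
]


@dataclass(frozen=True)
class DegConfig:
    min_abs_log2fc: float = 1.0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or not (0 < self.fdr_alpha < 1):
            raise ValueError("DEG thresholds must be positive (alpha in (0,1))")


def compute_tpm(counts: Sequence[float], effective_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts-per-million from counts and effective lengths.

    tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j); an all-zero count vector
    maps to all-zero TPM.  Scale-invariant in the counts.
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(effective_lengths, dtype=float)
    if c.shape != l.shape:
        raise ValueError("counts and lengths must align")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(l <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / l
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # Degenerate: no within-group variability.
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fold_change(mean_numerator: float, mean_denominator: float) -> float:
    """Plain ratio of group means; NaN flags an undefined (zero) denominator."""
    if mean_denominator == 0:
        return float("nan")
    return mean_numerator / mean_denominator


def round_fold(fc: float, style: str = "decimal") -> float:
    """Display rounding: 'decimal' -> 2 decimals, 'whole' -> nearest whole fold."""
    if style == "decimal":
        return round(fc, 2)
    if style == "whole":
        return float(round(fc))
    raise ValueError(f"unknown style {style!r}")


def deg_call(log2fc: float, q: float, config: DegConfig = DegConfig()) -> bool:
    """True iff |log2FC| > threshold and q < alpha (both strict)."""
    return abs(log2fc) > config.min_abs_log2fc and q < config.fdr_alpha


def expression_stats_table(tpm: pd.DataFrame, groups: Sequence[str],
                           config: DegConfig = DegConfig()) -> pd.DataFrame:
    """Per-transcript PA-vs-CN statistics from a TPM matrix.

    ``tpm`` is transcripts x samples; ``groups`` labels each column "PA" or
    "CN".  Output columns: mean_pa, mean_cn, fc (PA/CN), log2fc, t, p, q,
    deg_flag.  Transcripts with zero variance in both groups and equal
    means get t = 0, p = 1.
    """
    groups = list(groups)
    if len(groups) != tpm.shape[1]:
        raise ValueError("one group label per sample column required")
    if set(groups) - {"PA", "CN"}:
        raise ValueError("group labels must be 'PA' or 'CN'")
    pa = tpm.loc[:, [g == "PA" for g in groups]].to_numpy(dtype=float)
    cn = tpm.loc[:, [g == "CN" for g in groups]].to_numpy(dtype=float)
    rows = []
    for i, tid in enumerate(tpm.index):
        t, _, p = welch_t(pa[i], cn[i])
        m_pa, m_cn = pa[i].mean(), cn[i].mean()
        fc = fold_change(m_pa, m_cn)
        log2fc = math.log2(fc) if fc > 0 else float("nan")
        rows.append((tid, m_pa, m_cn, fc, log2fc, t, p))
    df = pd.DataFrame(rows, columns=["transcript_id", "mean_pa", "mean_cn",
                                     "fc", "log2fc", "t", "p"]).set_index("transcript_id")
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["deg_flag"] = [
        deg_call(l2, q, config) if not math.isnan(l2) else False
        for l2, q in zip(df["log2fc"], df["q"])
    ]
    return df
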