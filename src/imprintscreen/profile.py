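"""Per-CpG methylation tracks, coverage filtering, promoter and metagene
summaries, and ranking of transcripts by the PA/CN methylation ratio.

The screen logic: a maternally imprinted promoter is ~fully methylated in a
bimaternal (PA) sample and ~half methylated in a biparental (CN) sample, so
the ratio of group-mean promoter methylation (PA/CN) flags candidates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CpGCountRecord, ReadMethCall, Region, TranscriptModel

__all__ = [
    "MethylomeTrack",
    "ScreenConfig",
    "aggregate_per_cpg",
    "filter_coverage",
    "promoter_mean_methylation",
    "metagene_matrix",
    "rank_by_methylation_ratio",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the promoter methylation screen.

    Defaults: CpG sites need >= 3 covering reads; promoter = TSS +/- 2 kb;
    metagene profiles span 10 kb flanks in 100 bp bins with the body
    rescaled into 100 bins; candidate list keeps the top 100 transcripts
    with PA/CN ratio >= 1.2.
    """

    min_cov: int = 3
    promoter_halfwidth: int = 2000
    flank: int = 10000
    body_bins: int = 100
    flank_bin: int = 100
    top_n: int = 100
    min_ratio: float = 1.2
    ratio_pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_cov", "promoter_halfwidth", "flank", "body_bins",
                     "flank_bin", "top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_ratio <= 0 or self.ratio_pseudocount <= 0:
            raise ValueError("min_ratio and ratio_pseudocount must be positive")


class MethylomeTrack:
    """Sorted per-CpG methylated/unmethylated counts for one sample.

    Positions are unique and sorted; the methylation ratio is defined only
    where coverage is positive (which holds for every stored position).
    """

    def __init__(self, sample_id: str, positions: np.ndarray,
                 n_meth: np.ndarray, n_unmeth: np.ndarray):
        positions = np.asarray(positions, dtype=np.int64)
        n_meth = np.asarray(n_meth, dtype=np.int64)
        n_unmeth = np.asarray(n_unmeth, dtype=np.int64)
        if not (positions.shape == n_meth.shape == n_unmeth.shape):
            raise ValueError("positions and counts must have equal length")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(n_meth < 0) or np.any(n_unmeth < 0):
            raise ValueError("counts must be non-negative")
        self.sample_id = sample_id
        self.positions = positions
        self.n_meth = n_meth
        self.n_unmeth = n_unmeth

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def coverage(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def ratios(self) -> np.ndarray:
        cov = self.coverage
        out = np.full(cov.shape, np.nan)
        nz = cov > 0
        out[nz] = self.n_meth[nz] / cov[nz]
        return out

    def slice(self, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """(positions, ratios) of CpGs in [start, end)."""
        i0, i1 = np.searchsorted(self.positions, [start, end])
        return self.positions[i0:i1], self.ratios[i0:i1]

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[CpGCountRecord]) -> "MethylomeTrack":
        recs = sorted(records, key=lambda r: r.pos)
        return cls(
            sample_id,
            np.array([r.pos for r in recs], dtype=np.int64),
            np.array([r.n_meth for r in recs], dtype=np.int64),
            np.array([r.n_unmeth for r in recs], dtype=np.int64),
        )

    def to_records(self, chrom: str) -> List[CpGCountRecord]:
        return [
            CpGCountRecord(chrom, int(p), int(m), int(u))
            for p, m, u in zip(self.positions, self.n_meth, self.n_unmeth)
        ]


def aggregate_per_cpg(reads: Sequence[ReadMethCall],
                      sample_id: Optional[str] = None) -> MethylomeTrack:
    """Tally M/U calls per CpG position across reads of one sample."""
    sample_ids = {r.sample_id for r in reads}
    if len(sample_ids) > 1:
        raise ValueError(f"reads mix sample_ids: {sorted(sample_ids)}")
    if sample_id is None:
        sample_id = sample_ids.pop() if sample_ids else "empty"

    all_pos: List[int] = []
    all_meth: List[int] = []
    for r in reads:
        for p, s in r.cpg_calls:
            all_pos.append(p)
            all_meth.append(1 if s == "M" else 0)
    if not all_pos:
        empty = np.empty(0, dtype=np.int64)
        return MethylomeTrack(sample_id, empty, empty.copy(), empty.copy())
    pos = np.asarray(all_pos, dtype=np.int64)
    meth = np.asarray(all_meth, dtype=np.int64)
    uniq, inverse = np.unique(pos, return_inverse=True)
    n_meth = np.bincount(inverse, weights=meth).astype(np.int64)
    n_total = np.bincount(inverse).astype(np.int64)
    return MethylomeTrack(sample_id, uniq, n_meth, n_total - n_meth)


def filter_coverage(track: MethylomeTrack, min_cov: int) -> MethylomeTrack:
    """Keep exactly the CpG sites with coverage >= min_cov (idempotent)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    keep = track.coverage >= min_cov
    return MethylomeTrack(
        track.sample_id, track.positions[keep], track.n_meth[keep], track.n_unmeth[keep]
    )


def promoter_mean_methylation(track: MethylomeTrack, transcript: TranscriptModel,
                              halfwidth: int) -> Optional[float]:
    """Unweighted mean per-CpG ratio over [TSS - halfwidth, TSS + halfwidth).

    Returns None when the window holds no covered CpG; such transcripts are
    excluded from ranking.  Transcripts whose windows contain identical CpG
    sets necessarily get identical values.
    """
    _, ratios = track.slice(transcript.tss - halfwidth, transcript.tss + halfwidth)
    if ratios.size == 0:
        return None
    return float(np.mean(ratios))


def metagene_matrix(track: MethylomeTrack, transcripts: Sequence[TranscriptModel],
                    flank: int = 10000, flank_bin: int = 100,
                    body_bins: int = 100) -> pd.DataFrame:
    """Metagene methylation matrix: upstream flank, rescaled body, downstream flank.

    Fixed-width flank bins cover ``flank`` bp on each side of the body; the
    body (TSS..TES) is rescaled into ``body_bins`` equal fractions (short
    bodies contribute by nearest-fraction assignment).  Minus-strand
    transcripts are orientation-flipped so column 0 is always the far
    upstream end of the TSS flank.  Bins with no covered CpG are NaN.
    """
    n_flank = flank // flank_bin
    n_cols = 2 * n_flank + body_bins
    rows = np.full((len(transcripts), n_cols), np.nan)
    for i, t in enumerate(transcripts):
        lo, hi = t.body_start, t.body_end
        pos, ratios = track.slice(lo - flank, hi + flank)
        if pos.size == 0:
            continue
        cols = np.empty(pos.size, dtype=np.int64)
        up = pos < lo
        body = (pos >= lo) & (pos < hi)
        down = pos >= hi
        cols[up] = (pos[up] - (lo - flank)) // flank_bin
        # integer arithmetic: exact bin edges, mirror-symmetric
        scaled = (pos[body] - lo).astype(np.int64) * body_bins // (hi - lo)
        cols[body] = n_flank + np.minimum(scaled, body_bins - 1)
        cols[down] = n_flank + body_bins + np.minimum(
            (pos[down] - hi) // flank_bin, n_flank - 1
        )
        if t.strand == "-":
            cols = n_cols - 1 - cols
        sums = np.bincount(cols, weights=ratios, minlength=n_cols)
        counts = np.bincount(cols, minlength=n_cols)
        nz = counts > 0
        rows[i, nz] = sums[nz] / counts[nz]
    up_labels = [f"up{j}" for j in range(n_flank)]
    body_labels = [f"body{j}" for j in range(body_bins)]
    down_labels = [f"down{j}" for j in range(n_flank)]
    return pd.DataFrame(
        rows,
        index=[t.transcript_id for t in transcripts],
        columns=up_labels + body_labels + down_labels,
    )


def rank_by_methylation_ratio(
    pa_means: Mapping[str, Mapping[str, Optional[float]]],
    cn_means: Mapping[str, Mapping[str, Optional[float]]],
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Rank transcripts by the PA/CN promoter methylation ratio.

    ``pa_means``/``cn_means`` map sample_id -> (transcript_id -> promoter
    mean or None); the first PA key is the group's replicate 1.  Per-group
    means average the replicate promoter means; the ratio adds a small
    pseudocount to both terms.  The list is truncated to the top ``top_n``
    transcripts with ratio >= ``min_ratio`` and then re-sorted by the PA
    replicate-1 promoter mean (descending), matching how the screen
    surfaces loci whose bimaternal methylation is highest.  Ties break on
    transcript_id.
    """
    if not pa_means or not cn_means:
        raise ValueError("both groups need at least one sample")
    pa_samples = list(pa_means)
    cn_samples = list(cn_means)

    common: Optional[set] = None
    for sample_map in list(pa_means.values()) + list(cn_means.values()):
        defined = {t for t, v in sample_map.items() if v is not None}
        common = defined if common is None else (common & defined)
    eps = config.ratio_pseudocount

    rows = []
    for tid in sorted(common or ()):
        m_pa = float(np.mean([pa_means[s][tid] for s in pa_samples]))
        m_cn = float(np.mean([cn_means[s][tid] for s in cn_samples]))
        ratio = (m_pa + eps) / (m_cn + eps)
        rows.append((tid, m_pa, m_cn, ratio, float(pa_means[pa_samples[0]][tid])))
    df = pd.DataFrame(rows, columns=["transcript_id", "mean_pa", "mean_cn", "ratio", "pa1_mean"])
    df = df.sort_values(["ratio", "transcript_id"], ascending=[False, True], kind="mergesort")
    df = df.head(config.top_n)
    df = df[df["ratio"] >= config.min_ratio]
    df = df.sort_values(["pa1_mean", "transcript_id"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
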