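"""SNP-free read-level detection of allele-specific (hemi-)methylation.

Within one sample, reads over an allele-specifically methylated region
split into a near-fully methylated class (the methylated allele) and a
near-fully unmethylated class (the other allele) — detectable without any
sequence polymorphism.  The rule set:

* a *qualified read* carries >= 3 CpG calls inside the region;
* a read is *hypomethylated* when <= 20% of its in-region CpGs are
  methylated and *hypermethylated* when >= 80% are (inclusive bounds);
* a region needs more than 30 qualified reads to be judged at all, and is
  *hemi-methylated* when >= 30% of qualified reads are hypomethylated and
  >= 30% are hypermethylated;
* per-read pattern matrices require >= 10 reads each covering >= 3
  consecutive region CpGs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ReadMethCall, Region

__all__ = [
    "HemiConfig",
    "ReadClassification",
    "HemiCall",
    "qualify_reads",
    "classify_read",
    "classify_region",
    "pattern_matrix",
    "hemimeth_screen",
]

# Guard for exact threshold hits (e.g. 1 methylated of 5 CpGs == 0.20).
_EPS = 1e-12


@dataclass(frozen=True)
class HemiConfig:
    hypo_max: float = 0.20
    hyper_min: float = 0.80
    min_cpgs_per_read: int = 3
    min_qualified_reads: int = 31  # "more than 30" qualified reads
    hemi_class_frac: float = 0.30
    pattern_min_reads: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.hypo_max < self.hyper_min <= 1):
            raise ValueError("need 0 <= hypo_max < hyper_min <= 1")
        if self.hemi_class_frac > 0.5:
            raise ValueError("hemi_class_frac must be <= 0.5")
        if self.min_cpgs_per_read < 1 or self.min_qualified_reads < 1:
            raise ValueError("read/support minima must be >= 1")
        if self.pattern_min_reads < 1:
            raise ValueError("pattern_min_reads must be >= 1")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    n_cpgs: int
    mcpg_fraction: float
    klass: str  # "hypo" | "intermediate" | "hyper"


@dataclass(frozen=True)
class HemiCall:
    region: Region
    n_qualified: int
    frac_hypo: float
    frac_hyper: float
    status: str


def _in_region_calls(read: ReadMethCall, region: Optional[Region]):
    return read.cpg_calls if region is None else read.calls_in(region)


def qualify_reads(reads: Iterable[ReadMethCall], region: Region,
                  config: HemiConfig = HemiConfig()) -> List[ReadMethCall]:
    """Reads carrying >= min_cpgs_per_read CpG calls inside the region.

    Only in-region calls count: a read spanning the region border
    qualifies on its inside CpGs alone.
    """
    return [
        r for r in reads
        if len(_in_region_calls(r, region)) >= config.min_cpgs_per_read
    ]


def classify_read(read: ReadMethCall, config: HemiConfig = HemiConfig(),
                  region: Optional[Region] = None) -> ReadClassification:
    """Classify one qualified read as hypo-/intermediate/hypermethylated.

    The mCpG fraction uses in-region calls when a region is given; calls of
    the same read outside the region are ignored.
    """
    calls = _in_region_calls(read, region)
    n = len(calls)
    if n == 0:
        raise ValueError(f"read {read.read_id} has no CpG calls in scope")
    frac = sum(1 for _, s in calls if s == "M") / n
    if frac <= config.hypo_max + _EPS:
        klass = "hypo"
    elif frac >= config.hyper_min - _EPS:
        klass = "hyper"
    else:
        klass = "intermediate"
    return ReadClassification(read.read_id, n, frac, klass)


def classify_region(region: Region, reads: Iterable[ReadMethCall],
                    config: HemiConfig = HemiConfig()) -> HemiCall:
    """Judge a region's methylation architecture from its qualified reads.

    ``hemi_methylated`` needs both read classes at >= hemi_class_frac of
    qualified reads; a class at >= 80% of reads makes the region
    hyper-/hypo-dominant (full methylation / no methylation archetypes);
    fewer than min_qualified_reads gives ``insufficient_support``.
    Fractions are over all qualified reads, intermediates included.
    """
    qualified = qualify_reads(reads, region, config)
    n = len(qualified)
    if n < config.min_qualified_reads:
        return HemiCall(region, n, 0.0, 0.0, "insufficient_support")
    klasses = [classify_read(r, config, region).klass for r in qualified]
    frac_hypo = klasses.count("hypo") / n
    frac_hyper = klasses.count("hyper") / n
    if frac_hypo >= config.hemi_class_frac - _EPS and frac_hyper >= config.hemi_class_frac - _EPS:
        status = "hemi_methylated"
    elif frac_hyper >= 0.8 - _EPS:
        status = "hyper_dominant"
    elif frac_hypo >= 0.8 - _EPS:
        status = "hypo_dominant"
    else:
        status = "mixed_not_hemi"
    return HemiCall(region, n, frac_hypo, frac_hyper, status)


def pattern_matrix(region: Region, reads: Iterable[ReadMethCall],
                   config: HemiConfig = HemiConfig()) -> pd.DataFrame:
    """Per-read CpG state matrix over a region (M / U / '.' not covered).

    Rows are eligible reads — those covering >= min_cpgs_per_read
    *consecutive* region CpGs (no internal uncovered gap) — sorted by mCpG
    fraction descending then read_id; columns are the region's CpG
    positions (union of in-region calls over all supplied reads).  Raises
    when fewer than pattern_min_reads reads are eligible.
    """
    reads = list(reads)
    universe = sorted({p for r in reads for p, _ in _in_region_calls(r, region)})
    index = {p: i for i, p in enumerate(universe)}

    eligible: List[Tuple[float, str, Tuple[Tuple[int, str], ...]]] = []
    for r in reads:
        calls = _in_region_calls(r, region)
        if len(calls) < config.min_cpgs_per_read:
            continue
        idx = [index[p] for p, _ in calls]
        if idx[-1] - idx[0] + 1 != len(idx):  # internal not_covered gap
            continue
        frac = sum(1 for _, s in calls if s == "M") / len(calls)
        eligible.append((frac, r.read_id, calls))
    if len(eligible) < config.pattern_min_reads:
        raise ValueError(
            f"pattern matrix needs >= {config.pattern_min_reads} eligible reads, "
            f"got {len(eligible)} ({config.pattern_min_reads - len(eligible)} short)"
        )
    eligible.sort(key=lambda e: (-e[0], e[1]))
    matrix = np.full((len(eligible), len(universe)), ".", dtype=object)
    for row, (_, _, calls) in enumerate(eligible):
        for p, s in calls:
            matrix[row, index[p]] = s
    return pd.DataFrame(matrix, index=[rid for _, rid, _ in eligible], columns=universe)


def hemimeth_screen(regions: Sequence[Region],
                    reads_by_sample: Mapping[str, Sequence[ReadMethCall]],
                    config: HemiConfig = HemiConfig()) -> pd.DataFrame:
    """Hemi-methylation status of every region in every sample."""
    rows = []
    for sample_id in reads_by_sample:
        reads = reads_by_sample[sample_id]
        for region in regions:
            call = classify_region(region, reads, config)
            rows.append(
                (sample_id, region.chrom, region.start, region.end,
                 region.name, call.n_qualified, call.frac_hypo,
                 call.frac_hyper, call.status)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "region_name",
                 "n_qualified", "frac_hypo", "frac_hyper", "status"],
    )
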