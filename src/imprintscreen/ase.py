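"""Allele-specific expression at heterozygous SNPs.

Heterozygous sites are identified from genomic (DNA) allele counts; RNA
allele counts at those sites in the same individual then classify
expression as mono- or biallelic.  Monoallelic expression at every
informative SNP across tissues is the transcript-level signature of
imprinting.

The numeric rule (major-allele fraction >= 0.90 with binomial p < 0.01 for
monoallelic; minor fraction >= 0.20 for biallelic) is this package's own
conservative default — phase is not inferred, so monoallelic direction is
reported in ref/alt space unless strain-informative (phased) markers are
supplied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import binomtest

from .types import AlleleCountRecord, SnpRecord

__all__ = [
    "AseConfig",
    "AseCall",
    "call_het_snps",
    "classify_ase",
    "ase_summary",
    "ase_table",
]

MONOALLELIC = ("monoallelic_ref", "monoallelic_alt")


@dataclass(frozen=True)
class AseConfig:
    dna_min_depth: int = 10
    dna_het_minor_frac: float = 0.25
    rna_min_depth: int = 10
    mono_major_frac: float = 0.90
    bi_minor_frac: float = 0.20
    test_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.bi_minor_frac < 0.5 < self.mono_major_frac < 1):
            raise ValueError("need 0 < bi_minor_frac < 0.5 < mono_major_frac < 1")
        if self.dna_min_depth < 1 or self.rna_min_depth < 1:
            raise ValueError("depth minima must be >= 1")
        if not (0 < self.test_alpha < 1):
            raise ValueError("test_alpha must lie in (0, 1)")
        if not (0 < self.dna_het_minor_frac <= 0.5):
            raise ValueError("dna_het_minor_frac must lie in (0, 0.5]")


@dataclass(frozen=True)
class AseCall:
    snp: SnpRecord
    status: str  # monoallelic_ref | monoallelic_alt | biallelic | indeterminate
    major_frac: float
    p_binomial: float


def call_het_snps(dna_counts: Iterable[AlleleCountRecord],
                  config: AseConfig = AseConfig()) -> List[SnpRecord]:
    """Heterozygous SNPs from genomic allele counts.

    A site is HET when DNA depth >= dna_min_depth and the minor allele
    carries >= dna_het_minor_frac of the reads.
    """
    het: List[SnpRecord] = []
    for rec in dna_counts:
        if rec.assay != "DNA":
            raise ValueError("call_het_snps expects DNA-assay records")
        depth = rec.depth
        if depth < config.dna_min_depth:
            continue
        if min(rec.ref_count, rec.alt_count) / depth >= config.dna_het_minor_frac:
            het.append(
                SnpRecord(rec.snp.chrom, rec.snp.pos, rec.snp.ref_allele,
                          rec.snp.alt_allele, "HET")
            )
    return het


def classify_ase(snp: SnpRecord, rna_count: AlleleCountRecord,
                 config: AseConfig = AseConfig()) -> AseCall:
    """Classify allelic expression at one heterozygous SNP.

    Below rna_min_depth the call is indeterminate.  Otherwise monoallelic
    when the major allele holds >= mono_major_frac of reads and the exact
    two-sided binomial test against 0.5 rejects at test_alpha; biallelic
    when the minor allele holds >= bi_minor_frac; else indeterminate.
    Symmetric under ref/alt swap.
    """
    if rna_count.assay != "RNA":
        raise ValueError("classify_ase expects an RNA-assay record")
    if snp.genotype != "HET":
        raise ValueError(f"SNP {snp.chrom}:{snp.pos} is not heterozygous")
    depth = rna_count.depth
    if depth < config.rna_min_depth:
        return AseCall(snp, "indeterminate", float("nan"), float("nan"))
    major = max(rna_count.ref_count, rna_count.alt_count)
    major_frac = major / depth
    p = binomtest(rna_count.ref_count, depth, 0.5).pvalue
    if major_frac >= config.mono_major_frac and p < config.test_alpha:
        status = ("monoallelic_ref" if rna_count.ref_count >= rna_count.alt_count
                  else "monoallelic_alt")
    elif 1.0 - major_frac >= config.bi_minor_frac:
        status = "biallelic"
    else:
        status = "indeterminate"
    return AseCall(snp, status, major_frac, float(p))


def ase_summary(calls: Iterable[Tuple[str, AseCall]]) -> str:
    """Transcript-level verdict from per-(tissue, SNP) calls.

    ``calls`` pairs a tissue/individual label with each AseCall.  The
    verdict is ``imprinted_candidate`` when every informative call is
    monoallelic (direction may differ across individuals: phase is
    unknown), ``biallelic`` when biallelic calls occur in at least two
    tissues, else ``inconclusive``.
    """
    informative = [(tissue, c) for tissue, c in calls if c.status != "indeterminate"]
    if not informative:
        return "inconclusive"
    if all(c.status in MONOALLELIC for _, c in informative):
        return "imprinted_candidate"
    bi_tissues = {tissue for tissue, c in informative if c.status == "biallelic"}
    if len(bi_tissues) >= 2:
        return "biallelic"
    return "inconclusive"


def ase_table(calls: Sequence[Tuple[str, AseCall]]) -> pd.DataFrame:
    """Per-call table (tissue, chrom, pos, ref, alt, status, major_frac, p)."""
    return pd.DataFrame(
        [
            (tissue, c.snp.chrom, c.snp.pos, c.snp.ref_allele, c.snp.alt_allele,
             c.status, c.major_frac, c.p_binomial)
            for tissue, c in calls
        ],
        columns=["tissue", "chrom", "pos", "ref", "alt", "status", "major_frac", "p_binomial"],
    )
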