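"""Core domain records shared across the pipeline.

All coordinates are 0-based half-open internally; conversions to and from
1-based conventions (VCF) happen only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "Region",
    "TranscriptModel",
    "CpGCountRecord",
    "SnpRecord",
    "ReadMethCall",
    "AlleleCountRecord",
]

VALID_BASES = frozenset("ACGT")
VALID_GENOTYPES = frozenset({"HET", "HOM_REF", "HOM_ALT"})


@dataclass(frozen=True, order=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript anchor points for promoter windows and metagene profiles.

    ``tss``/``tes`` are genomic coordinates of the transcription start and
    end; for minus-strand transcripts the TSS is numerically greater than
    the TES.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"{self.transcript_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.transcript_id}: plus strand needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.transcript_id}: minus strand needs tss > tes")
        if self.biotype not in ("mRNA", "lncRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tes)

    def promoter(self, halfwidth: int) -> Region:
        """Promoter window [TSS - halfwidth, TSS + halfwidth), clipped at 0."""
        return Region(
            self.chrom,
            max(0, self.tss - halfwidth),
            self.tss + halfwidth,
            name=self.transcript_id,
        )


@dataclass(frozen=True)
class CpGCountRecord:
    """Per-CpG methylated/unmethylated read counts (dyad-merged, plus strand)."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(
                f"negative counts at {self.chrom}:{self.pos}: "
                f"({self.n_meth}, {self.n_unmeth})"
            )

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class SnpRecord:
    """Bi-allelic SNP with genotype, 0-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be A/C/G/T, got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        if self.genotype not in VALID_GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class ReadMethCall:
    """One aligned bisulfite read's CpG-level methylation calls.

    ``cpg_calls`` is an ordered tuple of ``(position, state)`` pairs with
    state ``"M"`` (methylated) or ``"U"`` (unmethylated), positions strictly
    increasing and inside ``[start, end)``.  ``allele_of_origin`` carries
    simulation truth and is absent for real data.
    """

    read_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    cpg_calls: Tuple[Tuple[int, str], ...]
    allele_of_origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start >= end")
        prev = None
        for pos, state in self.cpg_calls:
            if state not in ("M", "U"):
                raise ValueError(f"read {self.read_id}: bad state {state!r}")
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"read {self.read_id}: CpG {pos} outside [{self.start}, {self.end})"
                )
            if prev is not None and pos <= prev:
                raise ValueError(f"read {self.read_id}: positions not increasing")
            prev = pos

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_calls)

    @property
    def n_meth(self) -> int:
        return sum(1 for _, s in self.cpg_calls if s == "M")

    @property
    def mcpg_fraction(self) -> float:
        if not self.cpg_calls:
            raise ValueError(f"read {self.read_id} has no CpG calls")
        return self.n_meth / self.n_cpgs

    def calls_in(self, region: Region) -> Tuple[Tuple[int, str], ...]:
        """Calls falling inside ``region`` (same chromosome required)."""
        if region.chrom != self.chrom:
            return ()
        return tuple(
            (p, s) for p, s in self.cpg_calls if region.start <= p < region.end
        )


@dataclass(frozen=True)
class AlleleCountRecord:
    """Reference/alternative allele read counts at a SNP for one assay."""

    snp: SnpRecord
    sample_id: str
    assay: str  # "DNA" or "RNA"
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.assay not in ("DNA", "RNA"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count
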