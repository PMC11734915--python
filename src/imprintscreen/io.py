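"""Readers and writers for the on-disk dialects the pipeline touches.

Dialects (all plain tab-separated text):

* coverage files — Bismark-coverage style:
  ``chrom  start  end  meth_pct  n_meth  n_unmeth`` (0-based start; the
  percentage column is ignored on read and recomputed from counts),
* read-level methylation calls — project TSV with header
  ``read_id chrom start end cpg_positions cpg_states sample_id``,
* transcript tables — TSV with header
  ``transcript_id gene_id chrom strand tss tes biotype``,
* BED 3+1 regions,
* a VCF v4 subset (CHROM POS ID REF ALT QUAL FILTER INFO FORMAT sample,
  GT required; positions converted 1-based -> 0-based on read).

Every reader/writer pair round-trips losslessly.
"""
from __future__ import annotations

import os
from typing import Iterable, List, Optional, Sequence, Union

from .types import (
    AlleleCountRecord,
    CpGCountRecord,
    ReadMethCall,
    Region,
    SnpRecord,
    TranscriptModel,
)

__all__ = [
    "ParseError",
    "read_cov_file",
    "write_cov_file",
    "read_readlevel_tsv",
    "write_readlevel_tsv",
    "read_transcript_table",
    "write_transcript_table",
    "read_bed",
    "write_bed",
    "read_vcf_subset",
    "write_vcf_subset",
    "read_allele_counts",
    "write_allele_counts",
]

PathLike = Union[str, "os.PathLike[str]"]

READLEVEL_COLUMNS = (
    "read_id",
    "chrom",
    "start",
    "end",
    "cpg_positions",
    "cpg_states",
    "sample_id",
)
TRANSCRIPT_COLUMNS = ("transcript_id", "gene_id", "chrom", "strand", "tss", "tes", "biotype")

_GT_MAP = {"0/0": "HOM_REF", "0|0": "HOM_REF", "0/1": "HET", "1/0": "HET",
           "0|1": "HET", "1|0": "HET", "1/1": "HOM_ALT", "1|1": "HOM_ALT"}
_GT_BACK = {"HOM_REF": "0/0", "HET": "0/1", "HOM_ALT": "1/1"}


class ParseError(ValueError):
    """Malformed input line; carries the file path and 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _fields(line: str, n: int, path: PathLike, lineno: int, what: str) -> List[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n:
        raise ParseError(path, lineno, f"expected >= {n} tab-separated {what} fields, got {len(parts)}")
    return parts


def _int(value: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {value!r}") from None


# ---------------------------------------------------------------- coverage

def read_cov_file(path: PathLike) -> List[CpGCountRecord]:
    """Read a Bismark-coverage-style file into per-CpG count records."""
    records: List[CpGCountRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _fields(line, 6, path, lineno, "coverage")
            pos = _int(f[1], path, lineno, "start")
            n_meth = _int(f[4], path, lineno, "n_meth")
            n_unmeth = _int(f[5], path, lineno, "n_unmeth")
            try:
                records.append(CpGCountRecord(f[0], pos, n_meth, n_unmeth))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return records


def write_cov_file(path: PathLike, records: Iterable[CpGCountRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            cov = r.coverage
            pct = 100.0 * r.n_meth / cov if cov else 0.0
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{pct:.6g}\t{r.n_meth}\t{r.n_unmeth}\n")


# ---------------------------------------------------------------- read-level

def read_readlevel_tsv(path: PathLike) -> List[ReadMethCall]:
    """Read per-read CpG methylation calls from the project TSV dialect."""
    reads: List[ReadMethCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != READLEVEL_COLUMNS:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = _fields(line, 7, path, lineno, "read-level")
            positions = [] if f[4] == "" else [
                _int(p, path, lineno, "cpg position") for p in f[4].split(",")
            ]
            states = [] if f[5] == "" else f[5].split(",")
            if len(positions) != len(states):
                raise ParseError(
                    path, lineno,
                    f"{len(positions)} positions but {len(states)} states",
                )
            try:
                reads.append(
                    ReadMethCall(
                        read_id=f[0],
                        sample_id=f[6],
                        chrom=f[1],
                        start=_int(f[2], path, lineno, "start"),
                        end=_int(f[3], path, lineno, "end"),
                        cpg_calls=tuple(zip(positions, states)),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return reads


def write_readlevel_tsv(path: PathLike, reads: Iterable[ReadMethCall]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READLEVEL_COLUMNS) + "\n")
        for r in reads:
            positions = ",".join(str(p) for p, _ in r.cpg_calls)
            states = ",".join(s for _, s in r.cpg_calls)
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}\t{positions}\t{states}\t{r.sample_id}\n"
            )


# ---------------------------------------------------------------- transcripts

def read_transcript_table(path: PathLike) -> List[TranscriptModel]:
    transcripts: List[TranscriptModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRANSCRIPT_COLUMNS:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = _fields(line, 7, path, lineno, "transcript")
            try:
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f[0],
                        gene_id=f[1],
                        chrom=f[2],
                        strand=f[3],
                        tss=_int(f[4], path, lineno, "tss"),
                        tes=_int(f[5], path, lineno, "tes"),
                        biotype=f[6],
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return transcripts


def write_transcript_table(path: PathLike, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRANSCRIPT_COLUMNS) + "\n")
        for t in transcripts:
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\t{t.chrom}\t{t.strand}\t{t.tss}\t{t.tes}\t{t.biotype}\n"
            )


# ---------------------------------------------------------------- BED

def read_bed(path: PathLike) -> List[Region]:
    """Read BED 3+1 (name optional) into half-open 0-based regions."""
    regions: List[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = _fields(line, 3, path, lineno, "BED")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            try:
                regions.append(
                    Region(
                        f[0],
                        _int(f[1], path, lineno, "start"),
                        _int(f[2], path, lineno, "end"),
                        name,
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return regions


def write_bed(path: PathLike, regions: Iterable[Region]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name if r.name is not None else '.'}\n")


# ---------------------------------------------------------------- VCF subset

def read_vcf_subset(path: PathLike) -> List[SnpRecord]:
    """Read SNPs from a VCF v4 subset; positions become 0-based.

    Requires a FORMAT column containing GT and one sample column.  Only
    single-nucleotide REF/ALT records are accepted.
    """
    snps: List[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line, 10, path, lineno, "VCF")
            fmt = f[8].split(":")
            if "GT" not in fmt:
                raise ParseError(path, lineno, "missing GT in FORMAT")
            gt = f[9].split(":")[fmt.index("GT")]
            if gt not in _GT_MAP:
                raise ParseError(path, lineno, f"unsupported genotype {gt!r}")
            try:
                snps.append(
                    SnpRecord(
                        chrom=f[0],
                        pos=_int(f[1], path, lineno, "POS") - 1,
                        ref_allele=f[3],
                        alt_allele=f[4],
                        genotype=_GT_MAP[gt],
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return snps


ALLELE_COUNT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "genotype", "sample_id", "assay",
    "ref_count", "alt_count", "transcript_id",
)


def read_allele_counts(path: PathLike) -> List[tuple]:
    """Read DNA/RNA allele counts: list of (transcript_id, AlleleCountRecord).

    ``transcript_id`` may be "." for counts not tied to a transcript.
    """
    out: List[tuple] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALLELE_COUNT_COLUMNS:
            raise ParseError(path, 1, f"unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = _fields(line, 10, path, lineno, "allele-count")
            try:
                snp = SnpRecord(f[0], _int(f[1], path, lineno, "pos"), f[2], f[3], f[4])
                rec = AlleleCountRecord(
                    snp, f[5], f[6],
                    _int(f[7], path, lineno, "ref_count"),
                    _int(f[8], path, lineno, "alt_count"),
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append((f[9] if f[9] != "." else None, rec))
    return out


def write_allele_counts(path: PathLike, records: Iterable[tuple]) -> None:
    """Write (transcript_id or None, AlleleCountRecord) pairs."""
    with open(path, "w") as fh:
        fh.write("\t".join(ALLELE_COUNT_COLUMNS) + "\n")
        for tid, r in records:
            s = r.snp
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.genotype}\t"
                f"{r.sample_id}\t{r.assay}\t{r.ref_count}\t{r.alt_count}\t{tid if tid else '.'}\n"
            )


def write_vcf_subset(path: PathLike, snps: Iterable[SnpRecord], sample: str = "sample1") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\tGT\t{_GT_BACK[s.genotype]}\n"
            )
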