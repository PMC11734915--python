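"""Synthetic loci, diploid methylomes, bisulfite read sets, and ASE counts.

The generator works at methylation-call level (no nucleotide sequences, no
aligner): a diploid methylome is a pair of per-CpG methylation
probabilities (maternal, paternal allele), and each simulated read is drawn
wholly from one allele — the physical linkage that makes read-level
hemi-methylation detectable.  A bimaternal sample (parthenogenetic embryo)
draws both alleles from the maternal map; a biparental control draws one
maternal and one paternal.

A single symmetric flip probability (``conversion_error``) stands in for
bisulfite non-conversion plus sequencing error.

Archetype defaults for a maternally imprinted germline DMR: maternal allele
0.95 methylated per CpG, paternal 0.05, background 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import AlleleCountRecord, ReadMethCall, Region, SnpRecord, TranscriptModel

__all__ = [
    "SimConfig",
    "ImprintSpec",
    "AseSimTruth",
    "ScreenDataset",
    "simulate_locus",
    "simulate_diploid_methylome",
    "simulate_bisulfite_reads",
    "simulate_ase_counts",
    "simulate_screen_dataset",
]

PARENTAL_MODES = ("biparental", "bimaternal")


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one simulated bisulfite sample.

    ``depth`` is the expected number of reads covering each CpG;
    ``conversion_error`` is the probability that a true methylation state is
    flipped in the observed call.
    """

    seed: int = 0
    n_cpgs: int = 1000
    cpg_spacing: float = 20.0
    read_length: int = 150
    depth: float = 20.0
    conversion_error: float = 0.01
    parental_mode: str = "biparental"
    background_meth_p: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if self.cpg_spacing < 2:
            raise ValueError("cpg_spacing must be >= 2 bp")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.conversion_error < 0.5):
            raise ValueError("conversion_error must lie in [0, 0.5)")
        if self.parental_mode not in PARENTAL_MODES:
            raise ValueError(f"parental_mode must be one of {PARENTAL_MODES}")
        if not (0 <= self.background_meth_p <= 1):
            raise ValueError("background_meth_p must lie in [0, 1]")


@dataclass(frozen=True)
class ImprintSpec:
    """Allele-specific methylation probabilities over one region."""

    region: Region
    maternal_meth_p: float
    paternal_meth_p: float

    def __post_init__(self) -> None:
        for p in (self.maternal_meth_p, self.paternal_meth_p):
            if not (0 <= p <= 1):
                raise ValueError("methylation probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AseSimTruth:
    """Ground truth for one transcript's allelic expression.

    ``maternal_fraction`` is the probability that an RNA read comes from the
    maternal allele (1.0 = maternal-only, 0.0 = paternal-only, 0.5 =
    balanced biallelic); each SNP carries which allele the mother
    contributed.
    """

    transcript_id: str
    maternal_fraction: float
    snps: Tuple[Tuple[SnpRecord, str], ...]  # (snp, maternal_allele in {ref, alt})

    def __post_init__(self) -> None:
        if not (0 <= self.maternal_fraction <= 1):
            raise ValueError("maternal_fraction must lie in [0, 1]")
        for _, maternal in self.snps:
            if maternal not in ("ref", "alt"):
                raise ValueError(f"maternal_allele must be 'ref' or 'alt', got {maternal!r}")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _cpg_gap_positions(rng: np.random.Generator, start: int, n: int, spacing: float) -> np.ndarray:
    """CpG positions with geometric(1/spacing) gaps, floored at 2 bp."""
    gaps = np.maximum(rng.geometric(1.0 / spacing, size=n - 1), 2) if n > 1 else np.empty(0, int)
    return start + np.concatenate(([0], np.cumsum(gaps)))


def simulate_locus(
    config: SimConfig,
    n_transcripts: int = 1,
    chrom: str = "chrSim",
    origin: int = 1000,
) -> Tuple[np.ndarray, List[TranscriptModel], List[Region]]:
    """Lay out a locus: CpG positions, transcript models, and candidate regions.

    CpG positions are sorted, unique, with geometric(1/cpg_spacing) gaps of
    at least 2 bp.  Transcripts are placed on the plus strand in equal
    slices of the locus; each gets one candidate region (its promoter-scale
    window) for downstream planting of imprints.  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    positions = _cpg_gap_positions(rng, origin, config.n_cpgs, config.cpg_spacing)
    span_end = int(positions[-1]) + 1
    slice_len = max((span_end - origin) // max(n_transcripts, 1), 3)
    transcripts: List[TranscriptModel] = []
    regions: List[Region] = []
    for i in range(n_transcripts):
        s = origin + i * slice_len
        tss = s + slice_len // 3
        tes = min(tss + max(slice_len // 3, 1), s + slice_len - 1)
        if tes <= tss:
            tes = tss + 1
        transcripts.append(
            TranscriptModel(f"tx{i:04d}", f"gene{i:04d}", chrom, "+", tss, tes)
        )
        half = max(min(1000, slice_len // 6), 1)
        regions.append(Region(chrom, max(0, tss - half), tss + half, name=f"tx{i:04d}"))
    return positions, transcripts, regions


def simulate_diploid_methylome(
    cpg_positions: Sequence[int],
    imprint_specs: Sequence[ImprintSpec],
    background_meth_p: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-allele methylation probability maps over the locus CpGs.

    Inside each imprint region the maternal/paternal maps take that spec's
    probabilities; everywhere else both alleles sit at the background.
    Overlapping imprint regions are rejected.
    """
    specs = sorted(imprint_specs, key=lambda s: (s.region.chrom, s.region.start))
    for a, b in zip(specs, specs[1:]):
        if a.region.overlaps(b.region):
            raise ValueError(f"overlapping imprint regions: {a.region} / {b.region}")
    pos = np.asarray(cpg_positions)
    maternal = np.full(pos.shape, background_meth_p, dtype=float)
    paternal = np.full(pos.shape, background_meth_p, dtype=float)
    for spec in specs:
        mask = (pos >= spec.region.start) & (pos < spec.region.end)
        maternal[mask] = spec.maternal_meth_p
        paternal[mask] = spec.paternal_meth_p
    return maternal, paternal


def simulate_bisulfite_reads(
    maps: Tuple[np.ndarray, np.ndarray],
    cpg_positions: Sequence[int],
    config: SimConfig,
    sample_id: str,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chrSim",
    n_reads: Optional[int] = None,
) -> List[ReadMethCall]:
    """Draw bisulfite reads from a diploid methylome.

    Each read picks an allele uniformly — (maternal1, paternal) in
    biparental mode, (maternal1, maternal2) in bimaternal mode, where both
    maternal alleles use the maternal map — then calls each covered CpG
    methylated with the allele's probability and flips the observed state
    with probability ``conversion_error``.  Read starts are uniform over
    the locus so that expected per-CpG coverage equals ``depth``; reads
    covering zero CpGs are still emitted.
    """
    rng = _rng(config.seed if rng is None else rng)
    maternal, paternal = (np.asarray(m, dtype=float) for m in maps)
    pos = np.asarray(cpg_positions)
    if pos.size == 0:
        raise ValueError("no CpG positions")
    if maternal.shape != pos.shape or paternal.shape != pos.shape:
        raise ValueError("methylation maps must align with cpg_positions")

    rl = config.read_length
    lo = int(pos[0]) - rl + 1
    hi = int(pos[-1])  # inclusive upper bound on read start
    n_start = hi - lo + 1
    if n_reads is None:
        n_reads = int(round(config.depth * n_start / rl))

    if config.parental_mode == "bimaternal":
        allele_maps = (maternal, maternal)
        allele_names = ("maternal1", "maternal2")
    else:
        allele_maps = (maternal, paternal)
        allele_names = ("maternal1", "paternal")

    starts = rng.integers(lo, hi + 1, size=n_reads)
    alleles = rng.integers(0, 2, size=n_reads)
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, starts + rl)
    counts = i1 - i0
    total = int(counts.sum())
    u_meth = rng.random(total)
    u_flip = rng.random(total)
    offsets = np.concatenate(([0], np.cumsum(counts)))

    reads: List[ReadMethCall] = []
    for k in range(n_reads):
        a, b = offsets[k], offsets[k + 1]
        j0, j1 = i0[k], i1[k]
        probs = allele_maps[alleles[k]][j0:j1]
        methylated = u_meth[a:b] < probs
        observed = methylated ^ (u_flip[a:b] < config.conversion_error)
        calls = tuple(
            (int(p), "M" if m else "U")
            for p, m in zip(pos[j0:j1], observed)
        )
        reads.append(
            ReadMethCall(
                read_id=f"{sample_id}:r{k}",
                sample_id=sample_id,
                chrom=chrom,
                start=int(starts[k]),
                end=int(starts[k]) + rl,
                cpg_calls=calls,
                allele_of_origin=allele_names[alleles[k]],
            )
        )
    return reads


def simulate_ase_counts(
    truth: AseSimTruth,
    dna_depth: int,
    rna_depth: int,
    seed,
    sample_id: str = "sim",
) -> Tuple[List[AlleleCountRecord], List[AlleleCountRecord]]:
    """Draw DNA and RNA allele counts at each SNP of a transcript.

    DNA counts are Binomial(depth, 0.5) on ref vs alt (a true heterozygote);
    the RNA ref-allele probability is the maternal fraction if the maternal
    allele is ref, else its complement.
    """
    if dna_depth <= 0 or rna_depth <= 0:
        raise ValueError("depths must be positive")
    rng = _rng(seed)
    dna: List[AlleleCountRecord] = []
    rna: List[AlleleCountRecord] = []
    for snp, maternal_allele in truth.snps:
        d_ref = int(rng.binomial(dna_depth, 0.5))
        dna.append(AlleleCountRecord(snp, sample_id, "DNA", d_ref, dna_depth - d_ref))
        p_ref = truth.maternal_fraction if maternal_allele == "ref" else 1.0 - truth.maternal_fraction
        r_ref = int(rng.binomial(rna_depth, p_ref))
        rna.append(AlleleCountRecord(snp, sample_id, "RNA", r_ref, rna_depth - r_ref))
    return dna, rna


# ------------------------------------------------------------ screen dataset

@dataclass
class ScreenDataset:
    """A full synthetic input for the bimaternal-vs-biparental screen."""

    chrom: str
    cpg_positions: np.ndarray
    transcripts: List[TranscriptModel]
    imprinted_transcript_ids: List[str]
    gdmr_regions: List[Region]  # planted maternally methylated regions (truth)
    reads_by_sample: Dict[str, List[ReadMethCall]]
    groups: Dict[str, str]  # sample_id -> "PA" | "CN"


def simulate_screen_dataset(
    seed: int,
    n_genes: int = 50,
    n_imprinted: int = 1,
    gene_pitch: int = 6000,
    gdmr_halfwidth: int = 1000,
    maternal_meth_p: float = 0.95,
    paternal_meth_p: float = 0.05,
    n_pa: int = 2,
    n_cn: int = 2,
    config: Optional[SimConfig] = None,
    chrom: str = "chrSim",
) -> ScreenDataset:
    """Simulate a multi-gene locus with planted maternally imprinted genes.

    Genes sit on the plus strand at a fixed pitch; each imprinted gene
    carries a maternal germline DMR spanning TSS ± ``gdmr_halfwidth``
    (maternal allele ~fully methylated, paternal ~unmethylated).  PA samples
    are bimaternal, CN samples biparental; WGBS reads for every sample are
    drawn from the same locus.  Deterministic given ``seed``.
    """
    if not (0 <= n_imprinted <= n_genes):
        raise ValueError("need 0 <= n_imprinted <= n_genes")
    base = config if config is not None else SimConfig(seed=seed)
    rng = np.random.default_rng(seed)

    origin = max(base.read_length, 1000)
    span = n_genes * gene_pitch
    n_cpgs = int(span / base.cpg_spacing)
    positions = _cpg_gap_positions(rng, origin, n_cpgs, base.cpg_spacing)
    positions = positions[positions < origin + span]

    transcripts: List[TranscriptModel] = []
    for i in range(n_genes):
        tss = origin + i * gene_pitch + gene_pitch // 3
        tes = tss + gene_pitch // 3
        transcripts.append(TranscriptModel(f"tx{i:04d}", f"gene{i:04d}", chrom, "+", tss, tes))

    imprinted_idx = sorted(rng.choice(n_genes, size=n_imprinted, replace=False).tolist())
    gdmrs = [
        Region(chrom, transcripts[i].tss - gdmr_halfwidth, transcripts[i].tss + gdmr_halfwidth,
               name=transcripts[i].transcript_id)
        for i in imprinted_idx
    ]
    specs = [ImprintSpec(r, maternal_meth_p, paternal_meth_p) for r in gdmrs]
    maps = simulate_diploid_methylome(positions, specs, base.background_meth_p)

    reads_by_sample: Dict[str, List[ReadMethCall]] = {}
    groups: Dict[str, str] = {}
    samples = [(f"PA{i + 1}", "bimaternal") for i in range(n_pa)]
    samples += [(f"CN{i + 1}", "biparental") for i in range(n_cn)]
    for sample_id, mode in samples:
        cfg = replace(base, parental_mode=mode)
        reads_by_sample[sample_id] = simulate_bisulfite_reads(
            maps, positions, cfg, sample_id, rng=rng, chrom=chrom
        )
        groups[sample_id] = "PA" if mode == "bimaternal" else "CN"

    return ScreenDataset(
        chrom=chrom,
        cpg_positions=positions,
        transcripts=transcripts,
        imprinted_transcript_ids=[transcripts[i].transcript_id for i in imprinted_idx],
        gdmr_regions=gdmrs,
        reads_by_sample=reads_by_sample,
        groups=groups,
    )
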