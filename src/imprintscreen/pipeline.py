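"""End-to-end discovery flow and its configuration.

Stage order of the screen: aggregate read calls into per-CpG tracks ->
coverage filter -> per-sample promoter means -> PA/CN ratio ranking ->
DMR calling on the retained candidates' promoter windows -> read-level
hemi-methylation at the called DMRs.  Every run writes a manifest (seed,
config hash, package version, per-stage record counts) sufficient to
reproduce its outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
import numpy as np

from .ase import AseConfig
from .dmr import DmrCall, DmrConfig, call_dmrs, dmr_table, group_mean_diffs
from .hemimeth import HemiConfig, hemimeth_screen
from .profile import (
    MethylomeTrack,
    ScreenConfig,
    aggregate_per_cpg,
    filter_coverage,
    promoter_mean_methylation,
    rank_by_methylation_ratio,
)
from .simulate import SimConfig, simulate_screen_dataset
from .stats import DegConfig
from .types import ReadMethCall, Region, TranscriptModel

__all__ = [
    "PipelineConfig",
    "ScreenResult",
    "PlantedScreenOutcome",
    "run_screen",
    "evaluate_planted_screen",
]

logger = logging.getLogger("imprintscreen")

_CONFIG_SECTIONS = {
    "screen": ScreenConfig,
    "dmr": DmrConfig,
    "hemi": HemiConfig,
    "ase": AseConfig,
    "deg": DegConfig,
    "sim": SimConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for every stage plus run-level settings."""

    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    hemi: HemiConfig = field(default_factory=HemiConfig)
    ase: AseConfig = field(default_factory=AseConfig)
    deg: DegConfig = field(default_factory=DegConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        """Build from a nested mapping; unknown keys are rejected."""
        known = set(_CONFIG_SECTIONS) | {"seed"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        for section, klass in _CONFIG_SECTIONS.items():
            if section in data:
                sub = dict(data[section])
                valid = {f.name for f in dataclasses.fields(klass)}
                bad = set(sub) - valid
                if bad:
                    raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
                kwargs[section] = klass(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScreenResult:
    ranking: pd.DataFrame
    dmr_calls: List[DmrCall]
    hemi: pd.DataFrame
    manifest: Dict


def _stage_log(stage: str, **counts) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))


def partially_methylated_subregion(
    region: Region,
    tracks: Sequence[MethylomeTrack],
    lo: float = 0.25,
    hi: float = 0.75,
) -> Optional[Region]:
    """The span of CpGs inside ``region`` whose group-mean methylation is
    intermediate (in [lo, hi]) — a partially methylated region.

    In a biparental sample, allele-specific methylation shows up exactly as
    partial (~50%) methylation, so hemi-methylation is evaluated over this
    span rather than the raw DMR bounds, which can carry low-methylation
    flanking CpGs.  Returns None when no CpG qualifies.
    """
    positions = tracks[0].positions
    for t in tracks[1:]:
        positions = np.intersect1d(positions, t.positions, assume_unique=True)
    i0, i1 = np.searchsorted(positions, [region.start, region.end])
    positions = positions[i0:i1]
    if positions.size == 0:
        return None
    acc = np.zeros(positions.size)
    for t in tracks:
        idx = np.searchsorted(t.positions, positions)
        acc += t.ratios[idx]
    mean = acc / len(tracks)
    inside = positions[(mean >= lo) & (mean <= hi)]
    if inside.size == 0:
        return None
    return Region(region.chrom, int(inside[0]), int(inside[-1]) + 1, name=region.name)


def run_screen(
    reads_by_sample: Mapping[str, Sequence[ReadMethCall]],
    groups: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    config: PipelineConfig = PipelineConfig(),
    chrom: str = "chrSim",
) -> ScreenResult:
    """Run the PA-vs-CN discovery flow on in-memory inputs.

    ``groups`` maps each sample id to "PA" (bimaternal) or "CN"
    (biparental).  Returns the candidate ranking, promoter DMR calls on the
    retained candidates, and hemi-methylation calls at the DMRs.
    """
    bad = set(groups.values()) - {"PA", "CN"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    missing = set(reads_by_sample) - set(groups)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)}")

    tracks: Dict[str, MethylomeTrack] = {}
    for sample_id, reads in reads_by_sample.items():
        track = aggregate_per_cpg(reads, sample_id)
        tracks[sample_id] = filter_coverage(track, config.screen.min_cov)
        _stage_log("aggregate_filter", sample=sample_id, reads=len(reads),
                   cpgs_kept=len(tracks[sample_id]))

    half = config.screen.promoter_halfwidth
    means: Dict[str, Dict[str, Optional[float]]] = {
        s: {t.transcript_id: promoter_mean_methylation(tracks[s], t, half)
            for t in transcripts}
        for s in tracks
    }
    pa_samples = [s for s in reads_by_sample if groups[s] == "PA"]
    cn_samples = [s for s in reads_by_sample if groups[s] == "CN"]
    ranking = rank_by_methylation_ratio(
        {s: means[s] for s in pa_samples},
        {s: means[s] for s in cn_samples},
        config.screen,
    )
    _stage_log("rank", transcripts=len(transcripts), candidates=len(ranking))

    by_id = {t.transcript_id: t for t in transcripts}
    windows = [by_id[tid].promoter(half) for tid in ranking["transcript_id"]]
    dmr_calls = call_dmrs(
        [tracks[s] for s in pa_samples],
        [tracks[s] for s in cn_samples],
        windows,
        config.dmr,
        chrom=chrom,
    )
    _stage_log("dmr", windows=len(windows), calls=len(dmr_calls))

    cn_tracks = [tracks[s] for s in cn_samples]
    hemi_regions = []
    for i, call in enumerate(dmr_calls):
        named = Region(call.region.chrom, call.region.start, call.region.end,
                       name=f"dmr{i:03d}")
        refined = partially_methylated_subregion(named, cn_tracks)
        hemi_regions.append(refined if refined is not None else named)
    hemi = hemimeth_screen(hemi_regions, reads_by_sample, config.hemi)
    _stage_log("hemimeth", regions=len(hemi_regions), rows=len(hemi))

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "samples": {s: {"group": groups[s], "n_reads": len(reads_by_sample[s]),
                        "n_cpgs_filtered": len(tracks[s])}
                    for s in reads_by_sample},
        "n_candidates": int(len(ranking)),
        "n_dmr_calls": int(len(dmr_calls)),
    }
    return ScreenResult(ranking=ranking, dmr_calls=dmr_calls, hemi=hemi, manifest=manifest)


def write_screen_result(result: ScreenResult, out_dir) -> None:
    """Write ranking/DMR/hemi tables and the run manifest under out_dir."""
    os.makedirs(out_dir, exist_ok=True)
    result.ranking.to_csv(os.path.join(out_dir, "candidates.tsv"), sep="\t", index=False)
    dmr_table(result.dmr_calls).to_csv(os.path.join(out_dir, "dmrs.tsv"), sep="\t", index=False)
    result.hemi.to_csv(os.path.join(out_dir, "hemimeth.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ----------------------------------------------------- planted-signal harness

@dataclass(frozen=True)
class PlantedScreenOutcome:
    """How one replicate of the synthetic screen recovered its planted gene."""

    n_dmr_calls: int
    n_dmrs_at_planted: int
    planted_in_ranking: bool
    cn_all_hemi: bool
    pa_all_hyper_dominant: bool

    @property
    def exact_dmr_recovery(self) -> bool:
        return self.n_dmr_calls == 1 and self.n_dmrs_at_planted == 1

    @property
    def full_recovery(self) -> bool:
        return self.exact_dmr_recovery and self.cn_all_hemi and self.pa_all_hyper_dominant


def evaluate_planted_screen(seed: int, config: PipelineConfig = PipelineConfig(),
                            **sim_kwargs) -> PlantedScreenOutcome:
    """One replicate: simulate the default screen dataset, run the screen,
    and score recovery of the single planted imprinted gene."""
    ds = simulate_screen_dataset(seed, **sim_kwargs)
    if len(ds.gdmr_regions) != 1:
        raise ValueError("harness expects exactly one planted imprinted gene")
    result = run_screen(ds.reads_by_sample, ds.groups, ds.transcripts, config, chrom=ds.chrom)
    planted = ds.gdmr_regions[0]
    at_planted = [c for c in result.dmr_calls if c.region.overlaps(planted)]

    cn_all_hemi = False
    pa_all_hyper = False
    if at_planted:
        dmr_region = at_planted[0].region
        sub = result.hemi[
            (result.hemi["start"] < dmr_region.end)
            & (result.hemi["end"] > dmr_region.start)
        ]
        cn = sub[sub["sample_id"].map(ds.groups) == "CN"]
        pa = sub[sub["sample_id"].map(ds.groups) == "PA"]
        cn_all_hemi = len(cn) > 0 and bool((cn["status"] == "hemi_methylated").all())
        pa_all_hyper = len(pa) > 0 and bool((pa["status"] == "hyper_dominant").all())

    return PlantedScreenOutcome(
        n_dmr_calls=len(result.dmr_calls),
        n_dmrs_at_planted=len(at_planted),
        planted_in_ranking=planted.name in set(result.ranking["transcript_id"]),
        cn_all_hemi=cn_all_hemi,
        pa_all_hyper_dominant=pa_all_hyper,
    )
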