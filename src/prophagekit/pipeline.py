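"""End-to-end orchestration: simulate -> detect -> curate -> activity ->
pairs -> variable loci, with a structured run report.

The pipeline is configuration-driven and deterministic: the same config
(including the seed) produces byte-identical stage outputs.  Every stage
reads the files the previous stage wrote, so partial runs can resume
from existing outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import io as pio
from .activity import call_activity
from .curation import curate_elements
from .detection import (
    BackgroundStats,
    DetectionParams,
    detect_elements,
    background_stats,
    segment_contigs,
)
from .params import CurationRule, MCLParams, SimilarityParams, params_to_dict
from .similarity import ProphageSeq, dereplicate, find_similar_pairs, summarize_pairs
from .synthetic import PlantedElement, SimulationConfig, simulate_clipped_alignments, simulate_depth_profile

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_prefix", "stages", "simulate", "detection", "curation",
    "similarity", "mcl", "paths",
}
_STAGES = ("simulate", "detect", "curate", "activity", "pairs")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_prefix: str = "run"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    simulate: SimulationConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    curation: CurationRule = field(default_factory=CurationRule)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    mcl: MCLParams = field(default_factory=MCLParams)
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        cfg.seed = int(d.get("seed", 0))
        cfg.out_prefix = d.get("out_prefix", "run")
        cfg.stages = list(d.get("stages", _STAGES))
        bad = [s for s in cfg.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if "simulate" in d and d["simulate"] is not None:
            sim = dict(d["simulate"])
            sim.setdefault("seed", cfg.seed)
            elements = [PlantedElement(**e) for e in sim.pop("planted_elements", [])]
            plasmids = [tuple(p) for p in sim.pop("plasmids", [])]
            cfg.simulate = SimulationConfig(
                planted_elements=elements, plasmids=plasmids, **sim
            )
        for name, klass in (("detection", DetectionParams), ("similarity", SimilarityParams),
                            ("mcl", MCLParams)):
            if name in d:
                setattr(cfg, name, klass(**d[name]))
        cfg.paths = dict(d.get("paths", {}))
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.snapshot(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "out_prefix": self.out_prefix,
            "stages": list(self.stages),
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "detection": params_to_dict(self.detection),
            "curation": params_to_dict(self.curation),
            "similarity": params_to_dict(self.similarity),
            "mcl": params_to_dict(self.mcl),
            "paths": dict(self.paths),
        }


@dataclass
class RunReport:
    seed: int
    config_hash: str
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    discards: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, out_dir: str | Path = ".") -> RunReport:
    """Run the enabled stages in dependency order.

    ``simulate`` writes depth/alignment/truth files; ``detect`` consumes
    the depth profile (simulated or supplied via ``paths['depth']``);
    ``activity`` scores the detected elements; ``pairs`` needs a prophage
    FASTA (``paths['fasta']``) and optional host metadata.  Missing
    inputs raise before any computation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / config.out_prefix
    report = RunReport(config.seed, config.config_hash(), parameters=config.snapshot())
    logger.info("pipeline start: seed=%d config=%s", config.seed, report.config_hash)

    # --- input checks before any computation -------------------------------
    if "detect" in config.stages and "simulate" not in config.stages:
        if "depth" not in config.paths:
            raise FileNotFoundError("detect stage needs paths['depth'] when simulate is disabled")
        if not Path(config.paths["depth"]).exists():
            raise FileNotFoundError(f"depth file not found: {config.paths['depth']}")
    if "pairs" in config.stages:
        if "fasta" not in config.paths or not Path(config.paths["fasta"]).exists():
            raise FileNotFoundError("pairs stage needs an existing paths['fasta']")

    profile = None
    truth = None
    if "simulate" in config.stages:
        if config.simulate is None:
            raise ValueError("simulate stage enabled but no simulate config given")
        profile, truth = simulate_depth_profile(config.simulate)
        comment = f"seed={config.simulate.seed} config={config.simulate.config_hash()}"
        pio.write_depth_tsv(profile, f"{prefix}.depth.tsv", comment)
        clip_records = simulate_clipped_alignments(
            truth, config.simulate.clip_reads_per_border, 150, config.simulate.seed
        )
        pio.write_alignment_tsv(clip_records, f"{prefix}.alignments.tsv")
        Path(f"{prefix}.truth.json").write_text(truth.to_json())
        report.stage_counts["simulate"] = {
            "contigs": len(profile.contigs),
            "planted_elements": len(truth.elements),
            "plasmid_contigs": len(truth.plasmid_contigs),
        }

    detection = None
    if "detect" in config.stages:
        if profile is None:
            profile = pio.read_depth_tsv(config.paths["depth"])
        clip_records = None
        aln_path = Path(f"{prefix}.alignments.tsv")
        if aln_path.exists():
            clip_records = pio.read_alignment_tsv(aln_path)
        detection = detect_elements(profile, config.detection, clip_records)
        for i, el in enumerate(detection.elements):
            el.element_id = f"element_{i:03d}"
        pio.write_elements_bed(
            detection.elements, f"{prefix}.elements.bed",
            f"seed={config.seed} config={report.config_hash}",
        )
        stats_dict = {
            k: dataclasses.asdict(v) for k, v in detection.segment_stats.items()
        }
        pio.write_json(
            {"genome_median": detection.genome_median, "segments": stats_dict},
            f"{prefix}.stats.json",
        )
        report.stage_counts["detect"] = {
            "elements": len(detection.elements),
            "segments": len(detection.segment_stats),
        }
        report.warnings.extend(detection.notes)

    if "activity" in config.stages and detection is not None and profile is not None:
        rows = []
        lengths = {c: profile.length(c) for c in profile.contigs}
        segments = segment_contigs(lengths, config.detection)
        for el in detection.elements:
            depths = profile[el.contig][el.start:el.end]
            if len(depths) == 0:
                report.discards.append(
                    {"stage": "activity", "element": el.element_id, "reason": "empty region"}
                )
                continue
            segs = [s for s in segments
                    if s.contig == el.contig and s.role == "background_eligible"]
            mid = (el.start + el.end) // 2
            home = next((s for s in segs if s.start <= mid < s.end), None)
            if home is None:  # plasmid contig: neighborhood = whole genome
                stats = BackgroundStats(detection.genome_median, 0.0, 0)
                copy_number = float(np.median(depths)) / detection.genome_median
                call = call_activity(el.element_id, depths, stats,
                                     detection.genome_median, max(copy_number, 1.0))
            else:
                stats = background_stats(profile[el.contig][home.start:home.end],
                                         config.detection)
                call = call_activity(el.element_id, depths, stats)
            rows.append(dataclasses.asdict(call))
        pd.DataFrame(rows).to_csv(f"{prefix}.activity.tsv", sep="\t", index=False)
        report.stage_counts["activity"] = {"calls": len(rows)}

    if "pairs" in config.stages:
        seqs = pio.read_fasta(config.paths["fasta"])
        prophages = [ProphageSeq(name, seq) for name, seq in sorted(seqs.items())]
        pairs = find_similar_pairs(prophages, config.similarity)
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]).to_csv(
            f"{prefix}.pairs.tsv", sep="\t", index=False
        )
        derep = dereplicate(prophages, config.similarity)
        pio.write_json(
            {"representatives": derep.representatives, "membership": derep.membership},
            f"{prefix}.derep.json",
        )
        summary = None
        if "hosts" in config.paths and Path(config.paths["hosts"]).exists():
            meta = pd.read_csv(config.paths["hosts"], sep="\t")
            summary = summarize_pairs(pairs, meta, [p.id for p in prophages])
            pio.write_json(summary, f"{prefix}.pair_summary.json")
        report.stage_counts["pairs"] = {
            "prophages": len(prophages),
            "pairs": len(pairs),
            "representatives": len(derep.representatives),
        }

    pio.write_json(report.to_dict(), f"{prefix}.report.json")
    return report


def summarize_realms(realms: list[str]) -> pd.DataFrame:
    """Counts and percentages (one decimal) per viral realm."""
    if not realms:
        logger.warning("summarize_realms: empty prophage set")
        return pd.DataFrame(columns=["realm", "count", "percent"])
    counts = pd.Series(realms).value_counts()
    total = counts.sum()
    return pd.DataFrame(
        {
            "realm": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)
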