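"""Multi-stage runs from a single validated config, with manifests.

A run config names an output directory, one seed, and the stages to
execute: simulate-screen -> count -> score for the screen arm, or
simulate-endseq -> resect for the End-seq arm.  Stage sections are plain
mappings; unknown keys and invalid values fail fast with the offending
field named.  Every run writes its resolved config and a manifest with a
content checksum per output file, so identical configs and inputs are
verifiably identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import endseq, scoring
from .library import load_library
from .quant import AnchorConfig, CountTable, count_reads, read_sample_sheet
from .simulate import (
    EndseqSimConfig,
    ScreenSimConfig,
    simulate_endseq,
    simulate_screen,
)

log = logging.getLogger("dsbscreen")

__all__ = ["RunConfig", "run_pipeline", "write_manifest", "ConfigError"]

_STAGES = ("simulate-screen", "simulate-endseq", "count", "score", "resect")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Validated, fully serializable parameters for one pipeline run."""

    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=list)
    screen_sim: dict[str, Any] = field(default_factory=dict)
    endseq_sim: dict[str, Any] = field(default_factory=dict)
    count: dict[str, Any] = field(default_factory=dict)
    score: dict[str, Any] = field(default_factory=dict)
    resect: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {
            "out_dir", "seed", "log_level", "stages",
            "screen_sim", "endseq_sim", "count", "score", "resect",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("missing required config field: out_dir")
        stages = raw.get("stages")
        if stages is None:
            stages = []
            if raw.get("screen_sim") is not None:
                stages.append("simulate-screen")
            if raw.get("count") is not None or "simulate-screen" in stages:
                stages.append("count")
            if raw.get("score") is not None or "count" in stages:
                stages.append("score")
            if raw.get("endseq_sim") is not None:
                stages += ["simulate-endseq", "resect"]
            elif raw.get("resect") is not None:
                stages.append("resect")
        for s in stages:
            if s not in _STAGES:
                raise ConfigError(f"stages: unknown stage {s!r}; choose from {_STAGES}")
        if not isinstance(raw.get("seed", 0), int):
            raise ConfigError("seed: must be an integer")
        return cls(
            out_dir=Path(raw["out_dir"]),
            seed=raw.get("seed", 0),
            log_level=str(raw.get("log_level", "INFO")),
            stages=list(stages),
            screen_sim=dict(raw.get("screen_sim") or {}),
            endseq_sim=dict(raw.get("endseq_sim") or {}),
            count=dict(raw.get("count") or {}),
            score=dict(raw.get("score") or {}),
            resect=dict(raw.get("resect") or {}),
        )

    def to_mapping(self) -> dict[str, Any]:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "log_level": self.log_level,
            "stages": list(self.stages),
            "screen_sim": self.screen_sim,
            "endseq_sim": self.endseq_sim,
            "count": self.count,
            "score": self.score,
            "resect": self.resect,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, files: list[Path]) -> Path:
    """Write ``manifest.json`` mapping each output path to its sha256."""
    entries = {
        str(p.relative_to(out_dir)) if p.is_relative_to(out_dir) else str(p): _sha256(p)
        for p in sorted(set(files))
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
    return path


def _build_dataclass(cls, section: dict[str, Any], name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigError(f"{name}: {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"{name}: {exc}") from None


def _require_file(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input file for {what}: {path}")
    return path


def run_pipeline(config: RunConfig | dict[str, Any]) -> dict[str, Path]:
    """Execute the configured stages; returns a name -> path map of outputs.

    Raises ``ConfigError`` on schema violations and ``FileNotFoundError``
    (naming the path) when a stage's input is missing.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_mapping(), sort_keys=True)
    )
    outputs: dict[str, Path] = {"resolved_config": out_dir / "resolved_config.yaml"}

    sim = None
    counts: CountTable | None = None

    if "simulate-screen" in config.stages:
        section = dict(config.screen_sim)
        section.setdefault("seed", config.seed)
        cfg = _build_dataclass(ScreenSimConfig, section, "screen_sim")
        log.info("simulating screen: %d guides, %d reads/sample",
                 cfg.n_genes * cfg.guides_per_gene, cfg.reads_per_sample)
        sim = simulate_screen(cfg, out_dir / "sim")
        outputs["library"] = sim.library_path
        outputs["screen_truth"] = sim.truth_path
        for s, p in sim.fastq_paths.items():
            outputs[f"fastq_{s}"] = p

    if "count" in config.stages:
        section = dict(config.count)
        anchor_keys = {
            "anchor5", "anchor3", "max_anchor_mismatches", "spacer_length_range",
        }
        anchor_section = {k: section.pop(k) for k in list(section) if k in anchor_keys}
        if "spacer_length_range" in anchor_section:
            anchor_section["spacer_length_range"] = tuple(anchor_section["spacer_length_range"])
        policy = section.pop("ambiguous_policy", "discard")
        mismatch = section.pop("spacer_mismatch", 0)
        library_path = section.pop("library", None)
        sample_sheet = section.pop("samples", None)
        if section:
            raise ConfigError(f"count: unknown field(s) {sorted(section)}")
        if sim is not None:
            library_path = sim.library_path
            fastq_paths = {s: p for s, p in sim.fastq_paths.items()}
        if library_path is None:
            raise ConfigError("count: library path required (no simulate-screen stage)")
        index = load_library(_require_file(Path(library_path), "count.library"))
        if sim is None:
            if sample_sheet is None:
                raise ConfigError("count: samples sheet required (no simulate-screen stage)")
            fastq_paths, _roles = read_sample_sheet(
                _require_file(Path(sample_sheet), "count.samples")
            )
            for s, p in fastq_paths.items():
                _require_file(p, f"count sample {s!r}")
        if sim is not None and "anchor5" not in anchor_section:
            # match the simulator's layout so a combined run is coherent
            scfg = _build_dataclass(
                ScreenSimConfig, {**config.screen_sim, "seed": config.seed}, "screen_sim"
            )
            anchor_section.setdefault("anchor5", scfg.anchor5)
            anchor_section.setdefault("anchor3", scfg.anchor3)
            anchor_section.setdefault(
                "spacer_length_range", (scfg.spacer_length, scfg.spacer_length)
            )
        acfg = _build_dataclass(AnchorConfig, anchor_section, "count")
        log.info("counting %d sample(s) against %d guides", len(fastq_paths), len(index))
        counts = count_reads(fastq_paths, index, acfg,
                             ambiguous_policy=policy, spacer_mismatch=mismatch)
        counts_path = out_dir / "counts.tsv"
        counts.to_tsv(counts_path)
        counts.write_qc(out_dir / "counts_qc.json")
        outputs["counts"] = counts_path
        outputs["counts_qc"] = out_dir / "counts_qc.json"

    if "score" in config.stages:
        section = dict(config.score)
        numerator = section.pop("numerator", "high")
        denominator = section.pop("denominator", "low")
        statistic = section.pop("statistic", "median")
        threshold = section.pop("threshold", 4.0)
        counts_path = section.pop("counts", None)
        library_path = section.pop("library", None)
        if section:
            raise ConfigError(f"score: unknown field(s) {sorted(section)}")
        if counts is None:
            if counts_path is None:
                raise ConfigError("score: counts path required (no count stage)")
            counts = CountTable.from_tsv(_require_file(Path(counts_path), "score.counts"))
        if sim is not None:
            index = sim.library
        elif library_path is not None:
            index = load_library(_require_file(Path(library_path), "score.library"))
        else:
            # synthesize a one-gene-per-guide index from the counts table
            from .library import GuideRecord, build_index
            index = build_index(
                GuideRecord(g, counts.genes[g], "A")  # spacer unused for ranking
                for g in counts.counts.index
            )
        norm = scoring.normalize(counts)
        enr = scoring.enrichment(norm, numerator, denominator)
        summary = scoring.rank_genes(enr, index, statistic=statistic, threshold=threshold)
        paths = scoring.screen_report(counts, norm, enr, summary, out_dir)
        outputs.update({f"score_{k}": v for k, v in paths.items()})

    esim = None
    if "simulate-endseq" in config.stages:
        section = dict(config.endseq_sim)
        section.setdefault("seed", config.seed)
        ecfg = _build_dataclass(EndseqSimConfig, section, "endseq_sim")
        log.info("simulating End-seq: %d sites x %d ends (%s)",
                 ecfg.n_sites, ecfg.ends_per_site, ecfg.genotype)
        esim = simulate_endseq(ecfg, out_dir / "endseq_sim")
        outputs["sites_bed"] = esim.sites_path
        outputs["ends_bed"] = esim.ends_path
        outputs["endseq_truth"] = esim.truth_path

    if "resect" in config.stages:
        section = dict(config.resect)
        window = section.pop("window", endseq.DEFAULT_WINDOW)
        bin_size = section.pop("bin_size", endseq.DEFAULT_BIN_SIZE)
        quantile = section.pop("quantile", endseq.DEFAULT_QUANTILE)
        min_support = section.pop("min_support", endseq.DEFAULT_MIN_SUPPORT)
        sites_path = section.pop("sites", None)
        ends_path = section.pop("ends", None)
        if section:
            raise ConfigError(f"resect: unknown field(s) {sorted(section)}")
        if esim is not None:
            sites, ends = esim.sites, esim.ends
        else:
            if sites_path is None or ends_path is None:
                raise ConfigError("resect: sites and ends paths required (no simulate-endseq stage)")
            sites = endseq.read_sites_bed(_require_file(Path(sites_path), "resect.sites"))
            ends = endseq.read_ends_bed(_require_file(Path(ends_path), "resect.ends"))
        assigned = endseq.assign_ends(ends, sites, window=window)
        profiles = endseq.build_profiles(
            assigned, bin_size=bin_size, quantile=quantile, min_support=min_support
        )
        paths = write_resection_outputs(profiles, assigned, out_dir)
        outputs.update(paths)

    outputs["manifest"] = write_manifest(out_dir, [p for p in outputs.values()])
    return outputs


def write_resection_outputs(
    profiles: list[endseq.ResectionProfile],
    assigned: endseq.AssignedEnds,
    out_dir: Path,
) -> dict[str, Path]:
    """Write extent summary, per-site profile and heatmap matrix TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extent_rows = [
        {
            "site_id": p.site_id,
            "n_ends": p.n_ends,
            "extent_left": p.extent_left,
            "extent_right": p.extent_right,
            "extent": p.extent,
        }
        for p in profiles
    ]
    extent_path = out_dir / "extent_summary.tsv"
    pd.DataFrame(extent_rows).set_index("site_id").to_csv(
        extent_path, sep="\t", float_format="%.10g"
    )
    mat = endseq.heatmap_matrix(profiles, normalize="raw", sort="total_signal")
    heatmap_path = out_dir / "heatmap_matrix.tsv"
    mat.to_csv(heatmap_path, sep="\t", float_format="%.10g")
    stats_path = out_dir / "assignment_stats.json"
    stats_path.write_text(
        json.dumps(
            {
                "n_assigned": assigned.n_assigned,
                "n_unassigned": assigned.unassigned,
                "window": assigned.window,
                "n_sites": len(profiles),
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return {"extent_summary": extent_path, "heatmap_matrix": heatmap_path,
            "assignment_stats": stats_path}
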