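"""End-to-end orchestration: demultiplex → (align) → count → QC.

The pipeline wires the stages together under one configuration, records
a manifest (config hash, per-stage read accounting, output checksums)
and aborts naming the failing stage.  Alignment is an optional external
shell-out configured as a command template; the pipeline only consumes
the resulting tagged SAM files and never interprets aligner output
beyond that.  Re-running with identical inputs and configuration
reproduces identical matrices, which the manifest checksums make
checkable at a glance.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import yaml

from celseq2pipe.barcode_design import BarcodeSet, read_barcode_tsv
from celseq2pipe.demultiplex import ReadStructure, demultiplex_run
from celseq2pipe.qc_stats import (
    build_spikein_table,
    detection_curve,
    estimate_efficiency,
    gene_noise,
    select_high_variability,
)
from celseq2pipe.umi_count import CountMatrix, FeatureModel, count_run

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for a full run; every key mirrors a CLI flag."""

    r1_fastq: str
    r2_fastq: str
    barcodes_tsv: str
    gtf: str
    out_dir: str
    alignments: str | None = None  # existing tagged SAM (file or dir); skips align stage
    align_command: str | None = None  # template with {fastq} and {sam} placeholders
    umi_length: int = 6
    barcode_length: int = 6
    min_mapq: int = 10
    fix_slope: bool = False
    hvg_ratio: float = 1.5
    detection_bins: int = 10
    spikeins_tsv: str | None = None
    spike_prefix: str = "ERCC-"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for key in ("r1_fastq", "r2_fastq", "barcodes_tsv", "gtf"):
            path = getattr(self, key)
            if not Path(path).exists():
                raise PipelineError(f"validation: missing input {key}: {path}")
        if self.alignments is None and self.align_command is None:
            raise PipelineError(
                "validation: provide either pre-computed alignments or an align_command"
            )
        if self.alignments is not None and not Path(self.alignments).exists():
            raise PipelineError(f"validation: missing alignments: {self.alignments}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages and return (and write) the manifest."""
    from celseq2pipe import __version__

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": {},
        "valid": False,
    }
    manifest_path = out_dir / "manifest.json"

    def fail(stage: str, exc: Exception) -> PipelineError:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # demultiplex
    try:
        id_to_seq = read_barcode_tsv(config.barcodes_tsv)
        barcode_set = BarcodeSet.from_sequences(list(id_to_seq.values()))
        structure = ReadStructure(config.umi_length, config.barcode_length)
        demux_dir = out_dir / "demux"
        report = demultiplex_run(
            config.r1_fastq, config.r2_fastq, barcode_set, structure, demux_dir
        )
        report.to_tsv(out_dir / "demux_report.tsv")
        manifest["stages"]["demux"] = {
            "status": "ok",
            "total": report.total,
            "assigned": report.assigned,
            "unassigned": report.unassigned,
            "too_short": report.too_short,
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — manifest must record any stage failure
        raise fail("demux", exc) from exc

    # alignment (external, optional)
    try:
        if config.alignments is not None:
            align_path = Path(config.alignments)
            sam_files = sorted(align_path.glob("*.sam")) if align_path.is_dir() else [align_path]
        else:
            align_dir = out_dir / "aligned"
            align_dir.mkdir(exist_ok=True)
            sam_files = []
            for fq in sorted(demux_dir.glob("*.fastq")):
                sam = align_dir / (fq.stem + ".sam")
                cmd = config.align_command.format(fastq=fq, sam=sam)
                subprocess.run(cmd, shell=True, check=True)
                sam_files.append(sam)
        manifest["stages"]["align"] = {"status": "ok", "n_files": len(sam_files)}
    except Exception as exc:  # noqa: BLE001
        raise fail("align", exc) from exc

    # count
    try:
        model = FeatureModel.from_gtf(config.gtf)
        matrix, count_report = count_run(
            sam_files, model, umi_length=config.umi_length, min_mapq=config.min_mapq
        )
        counts_dir = out_dir / "counts"
        matrix.to_tsv(counts_dir)
        count_report.to_tsv(out_dir / "count_report.tsv")
        manifest["stages"]["count"] = {
            "status": "ok",
            "total_records": count_report.total,
            "assigned": count_report.assigned,
        }
    except Exception as exc:  # noqa: BLE001
        raise fail("count", exc) from exc

    # qc
    try:
        qc_dir = out_dir / "qc"
        qc_dir.mkdir(exist_ok=True)
        molecules = matrix.molecule_estimates
        is_spike = molecules.index.str.startswith(config.spike_prefix)
        endo = molecules.loc[~is_spike]
        if endo.shape[1] >= 2 and (endo.mean(axis=1) > 0).any():
            noise = gene_noise(endo)
            if len(noise) >= 10:
                noise = select_high_variability(noise, ratio=config.hvg_ratio)
            noise.round(6).to_csv(qc_dir / "gene_noise.tsv", sep="\t", index=False)
            detection_curve(endo, config.detection_bins).round(6).to_csv(
                qc_dir / "detection_curve.tsv", sep="\t", index=False
            )
        if config.spikeins_tsv:
            table = build_spikein_table(molecules, config.spikeins_tsv)
            table.round(6).to_csv(qc_dir / "spikein_table.tsv", sep="\t", index=False)
            fit = estimate_efficiency(table, fix_slope=config.fix_slope)
            fit.to_tsv(qc_dir / "efficiency.tsv")
            manifest["stages"]["qc"] = {"status": "ok", "efficiency": fit.efficiency}
        else:
            manifest["stages"]["qc"] = {"status": "ok", "efficiency": None}
    except Exception as exc:  # noqa: BLE001
        raise fail("qc", exc) from exc

    for path in sorted(out_dir.rglob("*.tsv")):
        manifest["outputs"][str(path.relative_to(out_dir))] = _sha256(path)
    manifest["valid"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
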