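"""End-to-end orchestration: regions → enrichment QC → harmonise →
prioritise → annotate, with a manifest for reproducibility.

``run_all`` drives the whole analysis from files on disk (the layout
written by :func:`targetsv.synthetic.write_bundle`, which is also the
layout a user prepares from real caller outputs) and writes a bundle of
tables plus a structured audit. Outputs are staged and moved into place
only on success, so a failing stage leaves no partial results. Identical
inputs give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotate import (
    TrackIndex,
    read_annotation_bed,
    summarise_annotations,
    window_overlap,
    window_report_table,
)
from .enrichment import (
    cohort_summary,
    enrichment_table,
    filter_reads,
    format_qc_report,
    read_reads_tsv,
)
from .harmonize import read_bam_evidence
from .ld import ld_blocks, read_haplotypes_tsv
from .prioritize import FilterConfig, read_impacts_tsv, run_cascade
from .regions import GenomicRegion, read_regions_bed
from .synthetic import load_bundle_calls

_CONFIG_KEYS = {
    "input_dir", "out_dir", "genome_size", "min_read_qual", "min_read_len",
    "qual_min", "indel_min_len", "annotation_window", "r2_threshold",
    "max_breakpoint_dist", "min_reciprocal_overlap", "disabled_stages",
}


@dataclass
class PipelineConfig:
    """One config governs every threshold (study defaults)."""

    input_dir: str
    out_dir: str
    genome_size: Optional[float] = None  # off-target coverage denominator
    min_read_qual: float = 9.0
    min_read_len: int = 500
    qual_min: float = 9.0
    indel_min_len: int = 10
    annotation_window: int = 2_500
    r2_threshold: float = 0.8
    max_breakpoint_dist: int = 500
    min_reciprocal_overlap: float = 0.5
    disabled_stages: tuple = ()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "input_dir" not in d or "out_dir" not in d:
            raise ValueError("config requires input_dir and out_dir")
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    tool_version: str
    started_at: str
    stage_counts: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_inputs(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*")) if p.is_file()
    }


@dataclass
class RunOutputs:
    out_dir: Path
    qc_table: pd.DataFrame
    qc_report: str
    prioritised: pd.DataFrame
    audit_json: str
    annotation_summary: pd.DataFrame
    manifest: RunManifest


def run_all(config: PipelineConfig) -> RunOutputs:
    """Run the full pipeline on a bundle directory; see module docstring."""
    root = Path(config.input_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input_dir {root} does not exist")
    manifest_digests = _digest_inputs(root)

    regions = read_regions_bed(root / "regions.bed")

    # Enrichment QC
    reads = read_reads_tsv(root / "reads.tsv") if (root / "reads.tsv").exists() else []
    kept, _removed = filter_reads(reads, config.min_read_qual, config.min_read_len)
    qc = enrichment_table(kept, regions, genome_size=config.genome_size)
    qc_report = ""
    if len(qc) >= 2:
        cohort = cohort_summary(qc[[c for c in qc.columns
                                    if not c.endswith("n_reads")]])
        qc_report = format_qc_report(qc, cohort)

    # Calls and evidence
    calls = load_bundle_calls(root)
    bam_path = root / "bam_evidence.tsv"
    bam_evidence = read_bam_evidence(bam_path) if bam_path.exists() else []
    impacts = read_impacts_tsv(root / "impacts.tsv") if (root / "impacts.tsv").exists() else []

    # LD blocks from haplotypes, one anchor per region
    blocks: list[GenomicRegion] = []
    anchors_path = root / "anchors.tsv"
    if anchors_path.exists():
        anchors = pd.read_csv(anchors_path, sep="\t")
        for row in anchors.itertuples():
            hap_path = root / "haplotypes" / f"{row.region}.tsv"
            if not hap_path.exists():
                continue
            haps = read_haplotypes_tsv(hap_path)
            for b in ld_blocks(haps, int(row.anchor_pos), config.r2_threshold):
                blocks.append(b.region)

    fc = FilterConfig(
        qual_min=config.qual_min, indel_min_len=config.indel_min_len,
        annotation_window=config.annotation_window,
        max_breakpoint_dist=config.max_breakpoint_dist,
        min_reciprocal_overlap=config.min_reciprocal_overlap,
        disabled_stages=frozenset(config.disabled_stages))
    result = run_cascade(calls, fc, impacts, blocks, regions,
                         bam_evidence=bam_evidence)

    # Annotation windows on the shortlist
    ann_path = root / "annotations.bed"
    tracks = TrackIndex(read_annotation_bed(ann_path) if ann_path.exists() else [])
    reports = [window_overlap(l, tracks, config.annotation_window)
               for l in result.loci]
    ann_summary = summarise_annotations(reports)
    windows = window_report_table(reports)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_digests=manifest_digests,
        tool_version=__version__,
        started_at=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        stage_counts=result.audit.counts(),
    )

    # Stage outputs, then move into place atomically.
    out_dir = Path(config.out_dir)
    staging = out_dir.with_name(out_dir.name + ".staging")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        qc.to_csv(staging / "qc_table.tsv", sep="\t")
        (staging / "qc_report.tsv").write_text(qc_report)
        result.table.to_csv(staging / "prioritised.tsv", sep="\t", index=False)
        (staging / "audit.json").write_text(result.audit.to_json())
        windows.to_csv(staging / "annotation_windows.tsv", sep="\t", index=False)
        ann_summary.to_csv(staging / "annotation_summary.tsv", sep="\t", index=False)
        (staging / "manifest.json").write_text(manifest.to_json())
        (staging / "report.md").write_text(render_report(
            regions, qc_report, result.table, result.audit, ann_summary))
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)

    return RunOutputs(out_dir=out_dir, qc_table=qc, qc_report=qc_report,
                      prioritised=result.table,
                      audit_json=result.audit.to_json(),
                      annotation_summary=ann_summary, manifest=manifest)


def render_report(regions, qc_report: str, prioritised: pd.DataFrame,
                  audit, ann_summary: pd.DataFrame) -> str:
    """Human-readable Markdown summary of one run."""
    lines = ["# Targeted sequencing variant prioritisation report", ""]
    lines += ["## Target regions", "",
              "| name | chrom | start | end | width (bp) |",
              "|---|---|---|---|---|"]
    for r in regions:
        lines.append(f"| {r.name} | {r.chrom} | {r.start:,} | {r.end:,} "
                     f"| {r.width:,} |")
    lines += ["", "## Sequencing QC (per sample, on/off target)", "",
              "```", qc_report.rstrip() or "(no reads supplied)", "```", ""]
    lines += ["## Prioritisation audit", "",
              "| stage | in | out |", "|---|---|---|"]
    for stage, n_in, n_out in audit.counts():
        lines.append(f"| {stage} | {n_in} | {n_out} |")
    lines += ["", f"## Prioritised variants ({len(prioritised)})", ""]
    if len(prioritised):
        lines += ["```", prioritised.to_string(index=False), "```"]
    else:
        lines.append("(none)")
    lines += ["", "## Annotation classes in shortlist windows", "",
              "```", ann_summary.to_string(index=False), "```", ""]
    return "\n".join(lines)
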