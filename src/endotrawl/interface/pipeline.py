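"""End-to-end funnel: screen -> recruit -> qc -> detect.

Datasets that fail the read prescreen short-circuit the rest of the run,
mirroring the dataset-selection funnel of the discovery procedure.  Every
stage writes machine-readable (JSON) and tabular (TSV) reports; the manifest
records input/output digests so that identical config + seed reproduces
identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import __version__
from ..aligncore import ScoringScheme, seeded_map
from ..detect import CoverageProfile, DetectionModel, call_presence, coverage_profile
from ..errors import EndotrawlError, InputError
from ..prescreen import STAGE1_MARKER, STAGE2_MARKER, screen_dataset
from ..quality import (
    MarkerSet,
    completeness_report,
    detect_rrna,
    find_orfs,
    score_markers,
)
from ..recruit import RecruitConfig, build_bin, detect_circularity, recruit_contigs
from .config import PipelineConfig
from .seqio import read_sequences, write_fasta

SCHEMA_VERSION = 1


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    schema: int = SCHEMA_VERSION
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, outputs: dict[str, str], **info) -> None:
        self.stages.append({"stage": name, "outputs": outputs, **info})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_reports(objects, outdir, name: str) -> dict[str, str]:
    """Write a list of report objects as JSON + TSV; returns path digests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [obj.to_dict() if hasattr(obj, "to_dict") else dict(obj) for obj in objects]
    json_path = outdir / f"{name}.json"
    json_path.write_text(
        json.dumps({"schema": SCHEMA_VERSION, "records": rows}, indent=2, default=str)
        + "\n"
    )
    tsv_path = outdir / f"{name}.tsv"
    with open(tsv_path, "w") as fh:
        if rows:
            keys = list(rows[0])
            fh.write("\t".join(keys) + "\n")
            for row in rows:
                fh.write("\t".join(str(row.get(k, "")) for k in keys) + "\n")
    return {str(p): _sha256(p) for p in (json_path, tsv_path)}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute screen -> recruit -> qc -> detect on the configured inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, started=_now())
    try:
        _run_stages(config, outdir, manifest)
    except EndotrawlError as exc:
        stage = manifest.stages[-1]["stage"] if manifest.stages else "setup"
        raise EndotrawlError(f"pipeline aborted after stage {stage!r}: {exc}") from exc
    manifest.finished = _now()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _run_stages(config: PipelineConfig, outdir: Path, manifest: RunManifest) -> None:
    for required in ("reads", "contigs", "references", "markers"):
        if getattr(config, required) is None:
            raise InputError(f"pipeline requires config.{required}")
    reads = [(r.id, r.seq) for r in read_sequences(config.reads)]
    contigs = {r.id: r.seq for r in read_sequences(config.contigs)}
    references = {r.id: r.seq for r in read_sequences(config.references)}
    markers = {r.id: r.seq for r in read_sequences(config.markers)}

    # --- screen ---------------------------------------------------------
    scheme = (
        ScoringScheme.protein()
        if config.screen_mode == "protein"
        else ScoringScheme.nucleotide()
    )
    report = screen_dataset(
        reads,
        markers,
        scheme,
        bsr_min=config.bsr_min,
        coverage_min=config.coverage_min,
        dataset_id=Path(config.reads).stem,
    )
    digests = write_reports([report], outdir, "screen")
    manifest.add_stage("screen", digests, verdict=report.verdict)
    if report.verdict != "pass":
        return

    # --- recruit --------------------------------------------------------
    rconfig = RecruitConfig(
        min_contig_len=config.min_contig_len,
        min_hit_columns=config.min_hit_columns,
        min_identity=config.min_identity,
        circular_overlap_min=config.circular_overlap_min,
    )
    recruited = recruit_contigs(contigs, references, rconfig)
    bins = {}
    bin_rows = []
    for rid in sorted(recruited):
        if not recruited[rid]:
            continue
        members = {cid: contigs[cid] for cid, _hit in recruited[rid]}
        bin_ = build_bin(members, rid)
        detect_circularity(bin_, rconfig)
        bins[bin_.bin_id] = bin_
        write_fasta(sorted(bin_.contigs.items()), outdir / f"{bin_.bin_id}.fasta")
        bin_rows.append(bin_.stats())
    digests = write_reports(bin_rows, outdir, "bins")
    for bin_id in bins:
        path = outdir / f"{bin_id}.fasta"
        digests[str(path)] = _sha256(path)
    manifest.add_stage("recruit", digests, n_bins=len(bins))
    if not bins:
        return

    # --- qc -------------------------------------------------------------
    marker_set_path = config.marker_set or config.markers
    set_records = read_sequences(marker_set_path)
    completeness_markers = [
        (r.id, r.seq)
        for r in set_records
        if config.marker_set is not None or r.id not in (STAGE1_MARKER, STAGE2_MARKER)
    ]
    marker_set = MarkerSet(completeness_markers)
    rrna_refs = (
        {r.id: r.seq for r in read_sequences(config.rrna_refs)}
        if config.rrna_refs
        else None
    )
    qc_reports = []
    for bin_id, bin_ in sorted(bins.items()):
        orfs = find_orfs(bin_.contigs, min_aa=config.orf_min_aa)
        counts = score_markers(
            [(o.orf_id, o.protein) for o in orfs], marker_set, bsr_min=config.qc_bsr_min
        )
        flags = detect_rrna(bin_.contigs, rrna_refs) if rrna_refs else None
        qc_reports.append(
            completeness_report(
                counts,
                marker_set,
                rrna_flags=flags,
                trna_count=config.trna_count,
                bin_stats=bin_.stats(),
                bin_id=bin_id,
            )
        )
    digests = write_reports(qc_reports, outdir, "qc")
    manifest.add_stage(
        "qc", digests, tiers={r.bin_id: r.tier for r in qc_reports}
    )

    # --- detect ---------------------------------------------------------
    model = DetectionModel(
        k=config.detect_k,
        tolerance=config.detect_tolerance,
        sidedness=config.detect_sidedness,
    )
    calls = []
    for bin_id, bin_ in sorted(bins.items()):
        hits = seeded_map(reads, bin_.contigs, k=config.map_seed_k)
        contig_order = sorted(bin_.contigs)
        offsets = {}
        total = 0
        for cid in contig_order:
            offsets[cid] = total
            total += len(bin_.contigs[cid])
        depth = np.zeros(total, dtype=np.int64)
        per_contig = {cid: [] for cid in contig_order}
        for hit in hits.values():
            if hit is not None and hit.ref_id in per_contig:
                per_contig[hit.ref_id].append(hit)
        for cid in contig_order:
            profile = coverage_profile(
                per_contig[cid], len(bin_.contigs[cid]), genome_id=cid
            )
            off = offsets[cid]
            depth[off : off + profile.length] = profile.depth
        combined = CoverageProfile(bin_id, total, depth)
        calls.append(call_presence(combined, model))
    digests = write_reports(calls, outdir, "detect")
    manifest.add_stage(
        "detect", digests, detected={c.genome_id: c.detected for c in calls}
    )
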