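"""End-to-end driver: plan generation and batch execution.

``generate_plans`` validates the whole batch up front (MDT, every file
config, reference availability) and fails fast — a config error in any row
aborts before any data is touched.  ``execute`` then runs the plans in one
of four modes:

- ``sequential``  — tracks one after another on one CPU;
- ``threaded``    — a thread pool across tracks;
- ``by_file``     — a process pool across tracks;
- ``by_chromosome`` — within each track, the row-wise stages run per
  normalized-chromosome partition (thread pool), and partitions are merged
  back in original row order before any whole-file stage (FDR grouping,
  interaction numbering, sorting, indexing).

All modes drive the same pure row functions, so final artifacts are
byte-identical regardless of mode or worker count.  Each track writes into
a private temporary directory that is moved into place only on success, so
a failing track never corrupts its siblings.
"""

from __future__ import annotations

import configparser
import logging
import shutil
import time
import uuid
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import core, interactions, metadata, qtl
from .config import (FileConfig, TrackDescriptor, load_vocabulary, parse_mdt,
                     parse_file_config, resolve_categories)
from .core import FORMAT_TYPES, build_output_path, normalize_chrom, read_mapped_rows
from .errors import HarmonizeError, ValidationError
from .refs import GeneModel, VariantReference

logger = logging.getLogger(__name__)

MODES = ("sequential", "threaded", "by_chromosome", "by_file")


@dataclass
class SystemConfig:
    """System-level configuration (reference paths and defaults).

    Mirrors an INI file with sections ``[references]`` (variant_reference,
    genome_fasta, gene_model, vocabulary) and ``[defaults]``
    (fdr_threshold).  All reference entries are optional until a QTL track
    actually needs them.
    """

    variant_reference: Path | None = None
    genome_fasta: Path | None = None
    gene_model: Path | None = None
    vocabulary: Path | None = None
    fdr_threshold: float = qtl.DEFAULT_FDR_THRESHOLD

    @classmethod
    def from_ini(cls, path) -> "SystemConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ValidationError(f"cannot read system config {path}")
        base = Path(path).resolve().parent
        refs = parser["references"] if "references" in parser else {}

        def _path(key):
            value = refs.get(key)
            return (base / value).resolve() if value else None

        defaults = parser["defaults"] if "defaults" in parser else {}
        return cls(
            variant_reference=_path("variant_reference"),
            genome_fasta=_path("genome_fasta"),
            gene_model=_path("gene_model"),
            vocabulary=_path("vocabulary"),
            fdr_threshold=float(defaults.get("fdr_threshold",
                                             qtl.DEFAULT_FDR_THRESHOLD)),
        )


@dataclass
class PipelinePlan:
    """One input file's resolved, inspectable processing plan."""

    track_id: str
    datatype: str
    stages: list
    input_path: Path
    config: FileConfig
    descriptor: TrackDescriptor
    output_paths: list
    chromosome_split_eligible: bool = True

    def describe(self) -> str:
        lines = [f"track {self.track_id} [{self.datatype}]",
                 f"  input:  {self.input_path}"]
        lines += [f"  stage:  {s}" for s in self.stages]
        lines += [f"  output: {p}" for p in self.output_paths]
        return "\n".join(lines)


@dataclass
class TrackResult:
    track_id: str
    status: str  # "ok" | "failed"
    error: str = ""
    n_rejects: int = 0
    metadata_rows: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)


@dataclass
class RunReport:
    results: list
    metadata_path: Path | None = None

    @property
    def ok(self) -> bool:
        return all(r.status == "ok" for r in self.results)

    def summary(self) -> str:
        lines = []
        for r in self.results:
            line = f"{r.track_id}: {r.status}"
            if r.status == "ok":
                line += f" ({len(r.metadata_rows)} track(s), {r.n_rejects} reject(s))"
            else:
                line += f" — {r.error}"
            lines.append(line)
        return "\n".join(lines)


_PRE_STAGES = ["read_input", "map_columns", "normalize_chrom", "convert_coordinates"]
_POST_STAGES = ["sort", "bgzip_compress", "tabix_index", "track_stats", "metadata"]
_TYPE_STAGES = {
    "intervals": [],
    "qtl": ["harmonize_alleles", "assign_rsid", "annotate_target",
            "compute_fdr", "split_variant_significance"],
    "interactions": ["assign_ids", "compute_score_value", "build_name",
                     "expand_anchors"],
}


def _plan_outputs(desc: TrackDescriptor, threshold: float) -> list:
    fmt_type = FORMAT_TYPES[desc.datatype]
    if desc.datatype == "qtl":
        tiers = ("full", f"FDR{threshold:g}")
        return [
            build_output_path(desc.track_id, "qtl", desc.assay_type,
                              desc.genome_build, significance_tier=tier,
                              variant_type=vt, format_type=fmt_type)
            for vt in ("SNP", "INDEL") for tier in tiers
        ]
    return [build_output_path(desc.track_id, desc.datatype, desc.assay_type,
                              desc.genome_build, format_type=fmt_type)]


def generate_plans(mdt_path, system: SystemConfig | None = None) -> list[PipelinePlan]:
    """One plan per MDT row; any validation problem aborts the whole batch."""
    system = system or SystemConfig()
    descriptors = parse_mdt(mdt_path)
    plans, problems = [], []
    for desc in descriptors:
        try:
            cfg = parse_file_config(desc.config_path, desc.datatype)
        except ValidationError as exc:
            problems.append(f"track {desc.track_id}: {exc}")
            continue
        if desc.datatype == "qtl":
            missing = [name for name, p in (
                ("variant_reference", system.variant_reference),
                ("genome_fasta", system.genome_fasta),
                ("gene_model", system.gene_model),
            ) if p is None or not Path(p).is_file()]
            if missing:
                problems.append(
                    f"track {desc.track_id}: QTL processing requires system "
                    f"reference(s): {', '.join(missing)}"
                )
                continue
        plans.append(PipelinePlan(
            track_id=desc.track_id,
            datatype=desc.datatype,
            stages=_PRE_STAGES + _TYPE_STAGES[desc.datatype] + _POST_STAGES,
            input_path=desc.file_path,
            config=cfg,
            descriptor=desc,
            output_paths=_plan_outputs(desc, system.fdr_threshold),
            chromosome_split_eligible=True,
        ))
    if problems:
        raise ValidationError("plan generation failed:\n  " + "\n  ".join(problems))
    return plans


def _partition_by_chrom(pairs):
    """Group (MappedRow, reject) pairs by normalized chromosome.

    Rejects and rows whose chromosome cannot be normalized go to a shared
    bucket; partition order is deterministic (sorted chromosome names).
    """
    buckets: dict[str, list] = {}
    leftovers = []
    for mapped, reject in pairs:
        if reject is not None:
            leftovers.append((mapped, reject))
            continue
        chrom_field = "chrom" if "chrom" in mapped.fields else "chrom1"
        try:
            chrom = normalize_chrom(mapped.fields.get(chrom_field, ""))
        except HarmonizeError:
            chrom = ""
        buckets.setdefault(chrom, []).append((mapped, None))
    return [buckets[c] for c in sorted(buckets)], leftovers


def _rowwise(plan: PipelinePlan, system: SystemConfig, pairs, resources):
    """Run the per-row stages on a batch of (MappedRow, reject) pairs."""
    if plan.datatype == "intervals":
        rows, rejects = core.process_interval_records(pairs, plan.config)
        return {"rows": rows, "rejects": rejects}
    if plan.datatype == "qtl":
        reference, genes = resources
        records, rejects, _ = qtl.process_qtl_records(
            pairs, plan.config, reference, genes,
            default_tissue=plan.descriptor.biosample_term,
        )
        return {"records": records, "rejects": rejects}
    records, rejects = interactions.parse_interactions(pairs, plan.config)
    return {"records": records, "rejects": rejects}


def run_plan(plan: PipelinePlan, system: SystemConfig, out_dir,
             by_chromosome: bool = False, partition_workers: int = 2) -> TrackResult:
    """Execute one plan: row-wise stages, whole-file stages, write + stats.

    Outputs are staged in a private temp directory and moved into
    ``out_dir`` only after every file of the track has been written.
    """
    out_dir = Path(out_dir)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    resources = None
    if plan.datatype == "qtl":
        resources = (
            VariantReference(system.variant_reference, system.genome_fasta),
            GeneModel(system.gene_model),
        )

    pairs = list(read_mapped_rows(plan.input_path, plan.config, plan.datatype))
    timings["read_and_map"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if by_chromosome and plan.chromosome_split_eligible:
        partitions, leftovers = _partition_by_chrom(pairs)
        with ThreadPoolExecutor(max_workers=max(1, partition_workers)) as pool:
            parts = list(pool.map(
                lambda part: _rowwise(plan, system, part, resources), partitions
            ))
        merged: dict[str, list] = {}
        for part in parts:
            for key, items in part.items():
                merged.setdefault(key, []).extend(items)
        merged.setdefault("rejects", []).extend(
            rej for _, rej in leftovers if rej is not None
        )
        # restore original input order before any whole-file stage
        if "rows" in merged:
            merged["rows"] = merged["rows"]  # intervals: order irrelevant (sorted later)
        if "records" in merged:
            merged["records"].sort(key=lambda r: r.lineno)
        merged["rejects"].sort(key=lambda r: r[0])
        stage_out = merged
    else:
        stage_out = _rowwise(plan, system, pairs, resources)
    timings["rowwise_stages"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rejects = stage_out.get("rejects", [])
    if plan.datatype == "qtl":
        records = qtl.compute_fdr(stage_out["records"])
        split = qtl.split_outputs(records, system.fdr_threshold)
        tiers = {"full": "full", "significant": f"FDR{system.fdr_threshold:g}"}
        outputs = {}
        for (vt, tier), recs in split.items():
            rel = build_output_path(
                plan.track_id, "qtl", plan.descriptor.assay_type,
                plan.descriptor.genome_build, significance_tier=tiers[tier],
                variant_type=vt, format_type=FORMAT_TYPES["qtl"],
            )
            outputs[rel] = [r.to_output_row() for r in recs]
    elif plan.datatype == "interactions":
        rows = interactions.finalize_interactions(
            stage_out["records"], plan.descriptor.data_source
        )
        outputs = {plan.output_paths[0]: rows}
    else:
        outputs = {plan.output_paths[0]: stage_out["rows"]}
    timings["wholefile_stages"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    staging = out_dir / f".tmp-{plan.track_id}-{uuid.uuid4().hex[:8]}"
    vocab = load_vocabulary(system.vocabulary)
    categories = resolve_categories(plan.descriptor.biosample_term, vocab)
    meta_rows = []
    try:
        for rel, rows in outputs.items():
            track = core.sort_compress_index(rows, staging / rel)
            meta_rows.append(metadata.assemble_metadata(
                plan.descriptor, categories, track, rel,
                FORMAT_TYPES[plan.datatype],
            ))
        core.write_rejects(rejects, staging / plan.track_id)
        # move every staged file into place only after all succeeded
        for staged in sorted(staging.rglob("*")):
            if staged.is_file():
                final = out_dir / staged.relative_to(staging)
                final.parent.mkdir(parents=True, exist_ok=True)
                shutil.move(str(staged), str(final))
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    timings["write_sort_index"] = time.perf_counter() - t0

    return TrackResult(
        track_id=plan.track_id, status="ok", n_rejects=len(rejects),
        metadata_rows=meta_rows, stage_seconds=timings,
    )


def _run_plan_safe(plan: PipelinePlan, system: SystemConfig, out_dir,
                   by_chromosome: bool = False) -> TrackResult:
    try:
        return run_plan(plan, system, out_dir, by_chromosome=by_chromosome)
    except Exception as exc:  # per-track isolation: report, don't propagate
        logger.error("track %s failed: %s", plan.track_id, exc)
        return TrackResult(track_id=plan.track_id, status="failed", error=str(exc))


def output_directories(out_dir) -> list[Path]:
    """Directories containing written tracks, one per output-hierarchy leaf.

    Hook for external collection-level interval indexers that build one
    index per directory of sorted BED files; the indexing call itself is
    out of scope here.
    """
    return sorted({p.parent for p in Path(out_dir).rglob("*.bed.gz")})


def execute(plans: list[PipelinePlan], out_dir, system: SystemConfig | None = None,
            mode: str = "sequential", threads: int = 2) -> RunReport:
    """Run all plans in the chosen mode and consolidate project metadata.

    A failing track is reported and skipped; the remaining tracks complete.
    ``RunReport.ok`` is False if any track failed.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown execution mode {mode!r}; choose from {MODES}")
    system = system or SystemConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if mode == "threaded":
        with ThreadPoolExecutor(max_workers=max(1, threads)) as pool:
            results = list(pool.map(
                lambda p: _run_plan_safe(p, system, out_dir), plans
            ))
    elif mode == "by_file":
        with ProcessPoolExecutor(max_workers=max(1, threads)) as pool:
            results = list(pool.map(
                _run_plan_safe, plans,
                [system] * len(plans), [out_dir] * len(plans),
            ))
    elif mode == "by_chromosome":
        results = [
            _run_plan_safe(p, system, out_dir, by_chromosome=True) for p in plans
        ]
    else:
        results = [_run_plan_safe(p, system, out_dir) for p in plans]

    meta_rows = [row for r in results for row in r.metadata_rows]
    meta_path = metadata.consolidate_project(meta_rows, out_dir) if meta_rows else None
    return RunReport(results=results, metadata_path=meta_path)
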