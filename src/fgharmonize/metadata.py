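"""Per-track statistics and standardized output metadata.

Each written track gets one metadata row: the descriptor's biological and
provenance fields, the resolved tissue/system categories, the output path
and the computed file statistics — record count, genomic base-pair coverage
(distinct bases covered by the track's intervals) and the md5 digest of the
uncompressed payload, so identity is independent of compression level.
All rows of a project are consolidated into a single TSV at the project
root.  The table carries no timestamps or hostnames, so reruns on unchanged
input are byte-identical.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import CategoryAssignment, TrackDescriptor
from .core import IndexedTrack
from .errors import ValidationError

METADATA_COLUMNS = (
    "output_path", "track_id", "datatype", "format_type",
    "biosample_term", "biosample_type", "life_stage", "assay_type",
    "tissue_category", "system_category", "genome_build",
    "data_source", "doi", "n_records", "bp_coverage", "md5",
    "track_description",
)


@dataclass
class TrackMetadata:
    descriptor: TrackDescriptor
    categories: CategoryAssignment
    output_path: str
    format_type: str
    n_records: int
    bp_coverage: int
    md5: str
    track_description: str

    def to_row(self) -> dict:
        d = self.descriptor
        return {
            "output_path": self.output_path,
            "track_id": d.track_id,
            "datatype": d.datatype,
            "format_type": self.format_type,
            "biosample_term": d.biosample_term,
            "biosample_type": d.biosample_type,
            "life_stage": d.life_stage,
            "assay_type": d.assay_type,
            "tissue_category": self.categories.tissue_category,
            "system_category": self.categories.system_category,
            "genome_build": d.genome_build,
            "data_source": d.data_source,
            "doi": d.doi,
            "n_records": self.n_records,
            "bp_coverage": self.bp_coverage,
            "md5": self.md5,
            "track_description": self.track_description,
        }


def compute_track_stats(track: IndexedTrack) -> tuple[int, int, str]:
    """(n_records, bp_coverage, md5) for a written, sorted track.

    Coverage is the size of the union of the [start, end) intervals,
    computed by a single streaming sweep over the coordinate-sorted rows
    (overlapping intervals counted once).  The digest is taken over the
    uncompressed payload.
    """
    n = 0
    coverage = 0
    digest = hashlib.md5()
    cur_chrom, cur_start, cur_end = None, 0, 0
    with gzip.open(track.data_path, "rb") as handle:
        for raw in handle:
            digest.update(raw)
            n += 1
            chrom, start, end = raw.decode().split("\t", 3)[:3]
            start, end = int(start), int(end)
            if chrom != cur_chrom or start > cur_end:
                coverage += cur_end - cur_start
                cur_chrom, cur_start, cur_end = chrom, start, end
            else:
                cur_end = max(cur_end, end)
    coverage += cur_end - cur_start
    return n, coverage, digest.hexdigest()


def serialize_description(extra: dict) -> str:
    """Extra MDT columns as ``key1=value1;key2=value2`` in MDT column order."""
    return ";".join(f"{k}={v}" for k, v in extra.items())


def assemble_metadata(descriptor: TrackDescriptor, categories: CategoryAssignment,
                      track: IndexedTrack, output_path, format_type: str) -> TrackMetadata:
    """Build the metadata row for one written track.

    A single input file can yield several tracks (QTL splitting); each gets
    its own row sharing the descriptor's source fields.
    """
    n, coverage, md5 = compute_track_stats(track)
    return TrackMetadata(
        descriptor=descriptor,
        categories=categories,
        output_path=str(output_path),
        format_type=format_type,
        n_records=n,
        bp_coverage=coverage,
        md5=md5,
        track_description=serialize_description(descriptor.extra),
    )


def consolidate_project(rows: list[TrackMetadata], project_dir) -> Path:
    """Write the single project-level metadata table (rows sorted by path)."""
    paths = [m.output_path for m in rows]
    dupes = sorted({p for p in paths if paths.count(p) > 1})
    if dupes:
        offenders = [
            f"{p} <- tracks {', '.join(m.descriptor.track_id for m in rows if m.output_path == p)}"
            for p in dupes
        ]
        raise ValidationError(
            "output path collision:\n  " + "\n  ".join(offenders)
        )
    table = pd.DataFrame(
        [m.to_row() for m in sorted(rows, key=lambda m: m.output_path)],
        columns=list(METADATA_COLUMNS),
    )
    out = Path(project_dir) / "metadata.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    return out
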