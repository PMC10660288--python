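"""Type-independent harmonization steps.

Every datatype goes through the same standard chain: read the input in its
declared dialect, map columns onto the standard field layout, normalize
chromosome names to the chr-prefixed scheme, convert coordinates to the
0-based half-open BED convention, then sort, bgzip-compress and tabix-index
the output.  Rows that cannot be harmonized are written to a ``.rejects``
sidecar with their line number and a reason; the run continues.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .config import FileConfig
from .errors import HarmonizeError, RowRejected, ValidationError

logger = logging.getLogger(__name__)

MISSING = "."

#: Standard output field layout per datatype.  QTL tracks use a fixed
#: 16-column layout ("bed19"-style extended BED); interaction tracks use the
#: UCSC interact layout with both anchors plus an anchor-id column.
OUTPUT_FIELDS = {
    "intervals": ("chrom", "start", "end", "name", "score", "strand"),
    "qtl": (
        "chrom", "start", "end", "name", "ref", "alt", "beta", "se",
        "pvalue", "fdr", "alt_allele_freq", "target_id", "gene_symbol",
        "target_strand", "tss_distance", "tissue",
    ),
    "interactions": (
        "chrom", "start", "end", "name", "score", "value", "experiment",
        "color", "source_chrom", "source_start", "source_end", "source_name",
        "source_strand", "target_chrom", "target_start", "target_end",
        "target_name", "target_strand", "anchor_id",
    ),
}

FORMAT_TYPES = {"intervals": "bed6plus", "qtl": "bed19", "interactions": "bedInteract"}


@dataclass
class GenomicInterval:
    """A normalized genomic interval: chr-prefixed name, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = MISSING
    score: str = MISSING
    strand: str = MISSING
    extra_fields: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RowRejected(
                "bad-interval", f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class IndexedTrack:
    """A written output track: bgzipped data + tabix index."""

    data_path: Path
    index_path: Path
    n_records: int
    sorted: bool = True


@dataclass
class MappedRow:
    """One input row after column mapping: standard fields + passthrough."""

    fields: dict
    passthrough: list
    lineno: int


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome label to the chr-prefixed scheme.

    ``"1"`` -> ``"chr1"``; ``"MT"``/``"chrMT"`` -> ``"chrM"``; ``"x"`` ->
    ``"chrX"``; already-normalized names pass through (idempotent).  Unknown
    contigs keep their spelling and gain a ``chr`` prefix if absent.
    """
    s = str(name).strip()
    if not s:
        raise RowRejected("empty-chromosome")
    body = s[3:] if s[:3].lower() == "chr" else s
    if not body:
        raise RowRejected("empty-chromosome", s)
    upper = body.upper()
    if upper in ("M", "MT"):
        return "chrM"
    if upper in ("X", "Y"):
        return "chr" + upper
    return "chr" + body


def convert_coordinates(start, end, base: int) -> tuple[int, int]:
    """Convert input coordinates to 0-based half-open.

    1-based inclusive ``(s, e)`` becomes ``(s-1, e)``; 0-based input passes
    through.  A single position (``end`` absent) becomes a 1-bp interval.
    """
    try:
        s = int(start)
        e = None if end is None or end == MISSING or end == "" else int(end)
    except (TypeError, ValueError):
        raise RowRejected("bad-coordinate", f"start={start!r} end={end!r}") from None
    if s < base:
        raise RowRejected("bad-coordinate", f"start {s} < coordinate base {base}")
    if e is None:
        s0 = s - base
        return s0, s0 + 1
    if e < s:
        raise RowRejected("bad-coordinate", f"end {e} < start {s}")
    if base == 1:
        return s - 1, e
    return s, e


def clamp_score(value: str) -> str:
    """Clamp a BED score to [0, 1000]; non-numeric values pass through as-is."""
    try:
        x = float(value)
    except (TypeError, ValueError):
        return MISSING if value in ("", None) else str(value)
    clamped = min(1000, max(0, int(round(x))))
    if clamped != x:
        logger.warning("score %s outside [0, 1000]; clamped to %d", value, clamped)
    return str(clamped)


class TableReader:
    """Stream (lineno, fields) rows from a delimited text file per a config.

    Resolves header names in the column map to 0-based indices on open.
    """

    def __init__(self, path, config: FileConfig, datatype: str):
        self.path = Path(path)
        self.config = config
        self.datatype = datatype
        self.index_map: dict[str, int] = {}
        self.passthrough_idx: list[int] = []
        self._resolved = False

    def _resolve(self, header: list[str] | None):
        def to_index(col, what):
            if isinstance(col, int):
                if col < 1:
                    raise ValidationError(f"{what}: column positions are 1-based")
                return col - 1
            if header is None:
                raise ValidationError(
                    f"{what}: column named {col!r} but has_header is false"
                )
            try:
                return header.index(col)
            except ValueError:
                raise ValidationError(
                    f"{what}: column {col!r} not found in header {header}"
                ) from None

        for out_field, col in self.config.column_map.items():
            self.index_map[out_field] = to_index(col, f"{self.path} [{out_field}]")
        for col in self.config.passthrough_columns:
            self.passthrough_idx.append(to_index(col, f"{self.path} [passthrough]"))
        self._resolved = True

    def __iter__(self):
        with open(self.path, newline="") as handle:
            reader = csv.reader(handle, delimiter=self.config.delimiter)
            lineno = 0
            header = None
            if self.config.has_header:
                try:
                    header = [h.strip() for h in next(reader)]
                except StopIteration:
                    self._resolve([])
                    return
                lineno = 1
            self._resolve(header)
            for row in reader:
                lineno += 1
                if row and any(f.strip() for f in row):
                    yield lineno, [f.strip() for f in row]


def map_columns(raw_row: list[str], reader: TableReader) -> MappedRow:
    """Apply a resolved column map to one raw row.

    Standard fields are populated from their mapped input columns; unmapped
    optional fields get the ``"."`` sentinel; passthrough columns are carried
    in configured order.  A row shorter than the highest mapped index is
    rejected (per-row, with line number attached by the caller).
    """
    needed = list(reader.index_map.values()) + reader.passthrough_idx
    highest = max(needed, default=-1)
    if len(raw_row) <= highest:
        raise RowRejected(
            "short-row", f"{len(raw_row)} fields, need at least {highest + 1}"
        )
    fields = {}
    for out_field, idx in reader.index_map.items():
        value = raw_row[idx]
        fields[out_field] = value if value != "" else MISSING
    passthrough = [raw_row[i] for i in reader.passthrough_idx]
    return MappedRow(fields=fields, passthrough=passthrough, lineno=-1)


def read_mapped_rows(path, config: FileConfig, datatype: str):
    """Yield ``(MappedRow, None)`` for good rows, ``(None, reject)`` for bad.

    A reject is ``(lineno, reason, raw_line)``.
    """
    reader = TableReader(path, config, datatype)
    for lineno, raw_row in reader:
        try:
            mapped = map_columns(raw_row, reader)
            mapped.lineno = lineno
            yield mapped, None
        except RowRejected as exc:
            yield None, (lineno, str(exc), config.delimiter.join(raw_row))


def normalize_row_location(mapped: MappedRow, config: FileConfig,
                           start_field="start", end_field="end",
                           chrom_field="chrom", pos_field=None) -> tuple[str, int, int]:
    """Normalize one row's chromosome + coordinates from its mapped fields."""
    chrom = normalize_chrom(mapped.fields.get(chrom_field, ""))
    if pos_field and pos_field in mapped.fields:
        start, end = convert_coordinates(mapped.fields[pos_field], None,
                                         config.coordinate_base)
    else:
        start_val = mapped.fields.get(start_field)
        end_val = mapped.fields.get(end_field)
        if start_val in (None, MISSING):
            raise RowRejected("bad-coordinate", "missing start")
        start, end = convert_coordinates(start_val, end_val, config.coordinate_base)
    return chrom, start, end


def process_interval_records(mapped_rows, config: FileConfig):
    """Row-wise harmonization for annotated-interval inputs.

    Intervals need nothing beyond the standard steps: chromosome and
    coordinate normalization, BED-style name/score/strand with the ``"."``
    sentinel for unmapped fields, score clamped to [0, 1000].

    Returns ``(rows, rejects)``.
    """
    rows, rejects = [], []
    for mapped, reject in mapped_rows:
        if reject is not None:
            rejects.append(reject)
            continue
        try:
            chrom, start, end = normalize_row_location(mapped, config)
            if start >= end:
                raise RowRejected("bad-interval", f"zero-length {chrom}:{start}-{end}")
            strand = mapped.fields.get("strand", MISSING)
            if strand not in ("+", "-", MISSING):
                raise RowRejected("bad-strand", strand)
            rows.append(
                [chrom, str(start), str(end),
                 mapped.fields.get("name", MISSING),
                 clamp_score(mapped.fields.get("score", MISSING)),
                 strand]
                + list(mapped.passthrough)
            )
        except RowRejected as exc:
            rejects.append((mapped.lineno, str(exc), MISSING))
    return rows, rejects


def sort_key(row: list[str]):
    """Deterministic total order: chrom lexicographic, start, end, full line."""
    return (row[0], int(row[1]), int(row[2]), "\t".join(row))


def write_rejects(rejects: list, out_path: Path) -> Path:
    """Write the rejects sidecar (lineno, reason, original line)."""
    sidecar = Path(str(out_path) + ".rejects")
    with open(sidecar, "w") as handle:
        handle.write("line\treason\traw\n")
        for lineno, reason, raw in rejects:
            handle.write(f"{lineno}\t{reason}\t{raw}\n")
    return sidecar


def sort_compress_index(records, out_path) -> IndexedTrack:
    """Sort records, write bgzip-compressed output and build a tabix index.

    ``records`` is an iterable of string-field rows whose first three fields
    are (chrom, start, end) in normalized form.  Rows are sorted by the
    deterministic total order of :func:`sort_key` (duplicates retained,
    adjacent).  An empty record set still yields a valid, indexed empty track.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(records, key=sort_key)
    plain = Path(str(out_path) + ".tmp")
    with open(plain, "w") as handle:
        for row in rows:
            handle.write("\t".join(row) + "\n")
    if not rows:
        logger.warning("writing empty track %s", out_path)
    pysam.tabix_compress(str(plain), str(out_path), force=True)
    os.remove(plain)
    pysam.tabix_index(str(out_path), preset="bed", force=True)
    return IndexedTrack(
        data_path=out_path,
        index_path=Path(str(out_path) + ".tbi"),
        n_records=len(rows),
    )


def query_track(track: IndexedTrack, chrom: str, start: int, end: int) -> list[list[str]]:
    """Region query through the tabix index; returns rows overlapping [start, end)."""
    with pysam.TabixFile(str(track.data_path)) as tbx:
        if chrom not in tbx.contigs:
            return []
        return [line.split("\t") for line in tbx.fetch(chrom, start, end)]


def build_output_path(track_id: str, datatype: str, assay_type: str,
                      genome_build: str, significance_tier: str | None = None,
                      variant_type: str | None = None,
                      format_type: str | None = None) -> Path:
    """Build the output-hierarchy relative path for one track.

    Component order: significance tier / variant type / assay type / format
    type / genome build / filename — with inapplicable components omitted
    (interval and interaction tracks carry no significance or variant-type
    tier).
    """
    if format_type is None:
        format_type = FORMAT_TYPES[datatype]
    build_label = genome_build.split("/")[0]
    parts = []
    if significance_tier:
        parts.append(_sanitize(significance_tier))
    if variant_type:
        parts.append(_sanitize(variant_type))
    parts.append(_sanitize(assay_type))
    parts.append(_sanitize(format_type))
    parts.append(_sanitize(build_label))
    parts.append(f"{_sanitize(track_id)}.bed.gz")
    return Path(*parts)


def _sanitize(component: str) -> str:
    out = str(component).strip().replace("/", "-").replace(" ", "_")
    if not out or out in (".", ".."):
        raise HarmonizeError(f"cannot use {component!r} as a path component")
    return out
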