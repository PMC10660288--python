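"""Chromatin-interaction normalization to an interact-style per-anchor layout.

Each interaction (a source anchor A and a target anchor B) is assigned a
unique 1-based ID in its order of appearance in the input, before any
sorting.  Both anchors are then written on separate lines keyed on their own
coordinates, so a region query at either end of a loop retrieves it; the
full interaction (both anchors, score, value, name) is carried on every
line, and the anchor-id column (``"<id>A"`` / ``"<id>B"``) ties the pair
back together after coordinate sorting separates them.

Score/value semantics follow the interact convention: score is an integer
in [0, 1000] (clamped when outside), value a double.  A missing value is
derived from the score as ``-log10(score)`` (null when score is 0); when an
input column is explicitly mapped as a p-value-like significance, that
takes precedence: ``value = -log10(p)`` and a missing score is derived as
``min(1000, round(-10 * log10(p)))``.  Whatever cannot be derived gets the
null sentinels (0 for score, "." for value).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .config import FileConfig
from .core import MISSING, MappedRow, clamp_score, normalize_chrom, convert_coordinates
from .errors import RowRejected

logger = logging.getLogger(__name__)


@dataclass
class InteractionRecord:
    interaction_id: int
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    score: int | None = None
    value: float | None = None
    pvalue_like: float | None = None
    experiment: str = MISSING
    color: str = "0"
    source_strand: str = MISSING
    target_strand: str = MISSING
    name: str = MISSING
    extra_fields: list = field(default_factory=list)
    lineno: int = -1


def _opt_float(fields: dict, name: str) -> float | None:
    value = fields.get(name, MISSING)
    if value in (MISSING, "", "NA", None):
        return None
    try:
        return float(value)
    except ValueError:
        raise RowRejected("bad-value", f"{name}={value!r}") from None


def parse_interaction_row(mapped: MappedRow, config: FileConfig) -> InteractionRecord:
    f = mapped.fields
    chrom1 = normalize_chrom(f.get("chrom1", ""))
    chrom2 = normalize_chrom(f.get("chrom2", ""))
    s1, e1 = convert_coordinates(f.get("start1"), f.get("end1"), config.coordinate_base)
    s2, e2 = convert_coordinates(f.get("start2"), f.get("end2"), config.coordinate_base)
    score_raw = f.get("score", MISSING)
    score = None
    if score_raw not in (MISSING, "", None):
        score = int(clamp_score(score_raw))
    rec = InteractionRecord(
        interaction_id=0,
        source_chrom=chrom1, source_start=s1, source_end=e1,
        target_chrom=chrom2, target_start=s2, target_end=e2,
        score=score,
        value=_opt_float(f, "value"),
        pvalue_like=_opt_float(f, "pvalue"),
        experiment=f.get("experiment", MISSING),
        color=f.get("color", "0") if f.get("color", MISSING) != MISSING else "0",
        source_strand=f.get("strand1", MISSING),
        target_strand=f.get("strand2", MISSING),
        extra_fields=mapped.passthrough,
        lineno=mapped.lineno,
    )
    if (chrom1, s1, e1) == (chrom2, s2, e2):
        logger.warning("line %d: self-interaction (identical anchors)", mapped.lineno)
    return rec


def assign_ids(records: list[InteractionRecord]) -> list[InteractionRecord]:
    """Number interactions 1..N by original appearance, before any sorting."""
    for i, rec in enumerate(records, start=1):
        rec.interaction_id = i
    return records


def compute_score_value(rec: InteractionRecord) -> InteractionRecord:
    """Fill missing score/value per the interact conventions (see module doc)."""
    if rec.value is None:
        if rec.pvalue_like is not None and rec.pvalue_like > 0:
            rec.value = -math.log10(rec.pvalue_like)
        elif rec.score is not None and rec.score > 0:
            rec.value = -math.log10(rec.score)
    if rec.score is None:
        if rec.pvalue_like is not None and rec.pvalue_like > 0:
            rec.score = min(1000, int(round(-10.0 * math.log10(rec.pvalue_like))))
        else:
            rec.score = 0  # null sentinel
    return rec


def build_name(rec: InteractionRecord, data_source: str) -> str:
    """Human-readable name: data source, ID, score and value, colon-joined."""
    value = f"{rec.value:.6g}" if rec.value is not None else MISSING
    score = rec.score if rec.score is not None else 0
    return f"{data_source}:{rec.interaction_id}:score={score}:value={value}"


def expand_anchors(rec: InteractionRecord) -> list[list[str]]:
    """Emit the two anchor lines (A = source, B = target) for one interaction.

    Both lines carry the complete interaction-level field set; only the
    leading query key (the anchor's own coordinates) and the anchor-id
    column differ.
    """
    value = f"{rec.value:.6g}" if rec.value is not None else MISSING
    shared = [
        rec.name, str(rec.score if rec.score is not None else 0), value,
        rec.experiment, rec.color,
        rec.source_chrom, str(rec.source_start), str(rec.source_end),
        f"{rec.interaction_id}A", rec.source_strand,
        rec.target_chrom, str(rec.target_start), str(rec.target_end),
        f"{rec.interaction_id}B", rec.target_strand,
    ]
    extras = [str(x) for x in rec.extra_fields]
    line_a = ([rec.source_chrom, str(rec.source_start), str(rec.source_end)]
              + shared + [f"{rec.interaction_id}A"] + extras)
    line_b = ([rec.target_chrom, str(rec.target_start), str(rec.target_end)]
              + shared + [f"{rec.interaction_id}B"] + extras)
    return [line_a, line_b]


def parse_interactions(mapped_rows, config: FileConfig):
    """Parse mapped rows into un-numbered records; returns (records, rejects)."""
    records, rejects = [], []
    for mapped, reject in mapped_rows:
        if reject is not None:
            rejects.append(reject)
            continue
        try:
            records.append(parse_interaction_row(mapped, config))
        except RowRejected as exc:
            rejects.append((mapped.lineno, str(exc), MISSING))
    return records, rejects


def finalize_interactions(records: list[InteractionRecord], data_source: str):
    """ID assignment (original appearance order), score/value, name, anchors.

    ``records`` must be in input order.  Returns the anchor rows (2 per
    interaction).
    """
    assign_ids(records)
    rows = []
    for rec in records:
        compute_score_value(rec)
        rec.name = build_name(rec, data_source)
        rows.extend(expand_anchors(rec))
    return rows


def process_interaction_records(mapped_rows, config: FileConfig, data_source: str):
    """Full interaction stage chain; returns (anchor_rows, rejects, n_interactions)."""
    records, rejects = parse_interactions(mapped_rows, config)
    rows = finalize_interactions(records, data_source)
    return rows, rejects, len(records)
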