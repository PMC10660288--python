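"""QTL-specific normalization.

Summary-statistics records are verified against a variant reference table
and re-oriented so that the effect statistics are always expressed on the
alternate allele: when a record's (ref, alt) pair is swapped relative to the
reference, the alleles are exchanged, the effect size is negated and the
alternate-allele frequency complemented.  Sites absent from the table fall
back to the genome sequence — if one stated allele equals the genome bases
at the record's coordinates, that allele is oriented as ref.  Records whose
alleles match neither route are unresolved and go to the rejects sidecar.

Resolved records then gain rsIDs (when the site is in the table), target
annotation (gene symbol, strand, signed TSS distance) and, where the input
carries no FDR column, a Benjamini–Hochberg adjusted p-value computed per
(target, tissue) group.  Finally records are split into SNP/INDEL full
tracks plus their significant subsets (FDR strictly below the threshold,
0.05 by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from statsmodels.stats.multitest import multipletests

from .config import FileConfig
from .core import MISSING, MappedRow, normalize_row_location
from .errors import RowRejected
from .refs import GeneModel, VariantReference

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_PALINDROME = ({"A", "T"}, {"C", "G"})

DEFAULT_FDR_THRESHOLD = 0.05


def fmt(x) -> str:
    """Canonical numeric rendering for output columns (6 significant digits)."""
    if x is None:
        return MISSING
    return f"{x:.6g}"


@dataclass
class QTLRecord:
    """One variant–target association, normalized to BED conventions."""

    chrom: str
    start: int
    end: int
    variant_id: str
    ref_allele: str
    alt_allele: str
    beta: float
    pvalue: float
    target_id: str
    tissue: str
    se: float | None = None
    fdr: float | None = None
    alt_allele_freq: float | None = None
    rsid: str | None = None
    gene_symbol: str = MISSING
    target_strand: str = MISSING
    tss_distance: int | None = None
    flip_status: str = "unresolved"
    passthrough: list = field(default_factory=list)
    lineno: int = -1

    @property
    def effect_allele(self) -> str:
        """After harmonization, statistics are expressed on the alt allele."""
        return self.alt_allele

    @property
    def variant_type(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "INDEL"

    def to_output_row(self) -> list[str]:
        return [
            self.chrom, str(self.start), str(self.end),
            self.rsid if self.rsid else self.variant_id,
            self.ref_allele, self.alt_allele,
            fmt(self.beta), fmt(self.se), fmt(self.pvalue), fmt(self.fdr),
            fmt(self.alt_allele_freq), self.target_id, self.gene_symbol,
            self.target_strand,
            str(self.tss_distance) if self.tss_distance is not None else MISSING,
            self.tissue,
        ] + list(self.passthrough)


def _parse_float(fields: dict, name: str, required: bool = False) -> float | None:
    value = fields.get(name, MISSING)
    if value in (MISSING, "", "NA", "nan", "NaN", None):
        if required:
            raise RowRejected("missing-value", name)
        return None
    try:
        return float(value)
    except ValueError:
        raise RowRejected("bad-value", f"{name}={value!r}") from None


def parse_qtl_row(mapped: MappedRow, config: FileConfig,
                  default_tissue: str) -> QTLRecord:
    """Build a QTLRecord from one mapped row; validates alleles and p-value.

    When the input provides a single position instead of start/end, the
    interval footprint is derived from the reference-allele length
    (``end = start + len(ref)``), so INDELs span their deleted bases.
    """
    ref = mapped.fields.get("ref", MISSING).upper()
    alt = mapped.fields.get("alt", MISSING).upper()
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
        raise RowRejected("bad-allele", f"ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise RowRejected("bad-allele", f"ref == alt == {ref!r}")

    use_pos = "pos" in mapped.fields
    chrom, start, end = normalize_row_location(
        mapped, config, pos_field="pos" if use_pos else None
    )
    if use_pos:
        end = start + len(ref)

    pvalue = _parse_float(mapped.fields, "pvalue", required=True)
    if not (0.0 < pvalue <= 1.0):
        raise RowRejected("bad-pvalue", f"{pvalue} outside (0, 1]")
    fdr = _parse_float(mapped.fields, "fdr")
    if fdr is not None and not (0.0 < fdr <= 1.0):
        raise RowRejected("bad-fdr", f"{fdr} outside (0, 1]")
    af = _parse_float(mapped.fields, "alt_allele_freq")
    if af is not None and not (0.0 <= af <= 1.0):
        raise RowRejected("bad-value", f"alt_allele_freq={af} outside [0, 1]")

    return QTLRecord(
        chrom=chrom, start=start, end=end,
        variant_id=mapped.fields.get("variant_id", MISSING),
        ref_allele=ref, alt_allele=alt,
        beta=_parse_float(mapped.fields, "beta", required=True),
        se=_parse_float(mapped.fields, "se"),
        pvalue=pvalue, fdr=fdr, alt_allele_freq=af,
        target_id=mapped.fields.get("target_id", MISSING),
        tissue=mapped.fields.get("tissue", MISSING) if
               mapped.fields.get("tissue", MISSING) != MISSING else default_tissue,
        passthrough=mapped.passthrough,
        lineno=mapped.lineno,
    )


def _swap(rec: QTLRecord) -> None:
    """Exchange ref/alt and re-express statistics on the new alt allele."""
    rec.ref_allele, rec.alt_allele = rec.alt_allele, rec.ref_allele
    rec.beta = -rec.beta
    if rec.alt_allele_freq is not None:
        rec.alt_allele_freq = 1.0 - rec.alt_allele_freq


def is_palindromic(rec: QTLRecord) -> bool:
    return {rec.ref_allele, rec.alt_allele} in _PALINDROME


def harmonize_alleles(rec: QTLRecord, ref: VariantReference) -> QTLRecord:
    """Verify and, when needed, re-orient a record's alleles.

    Mutates and returns ``rec``.  Outcomes (``flip_status``):

    - ``match``: (ref, alt) agrees with the reference site.
    - ``flipped``: alleles were swapped relative to the site; alleles
      exchanged, beta negated, alt frequency complemented.
    - ``genome_resolved``: site absent from the table, but one stated allele
      equals the genome bases at the coordinates; oriented accordingly.
    - ``unresolved``: no route agrees; caller sends the record to rejects.

    |beta| and the p-value are never altered; only sign, alleles and the
    allele-frequency complement change.
    """
    site = ref.lookup(rec.chrom, rec.start, rec.end)
    if site is not None:
        if rec.ref_allele == site.ref and rec.alt_allele in site.alts:
            rec.flip_status = "match"
        elif rec.alt_allele == site.ref and rec.ref_allele in site.alts:
            _swap(rec)
            rec.flip_status = "flipped"
        else:
            rec.flip_status = "unresolved"
        return rec

    genome = ref.genome_bases(rec.chrom, rec.start, rec.end)
    if genome:
        if rec.ref_allele == genome:
            rec.flip_status = "genome_resolved"
        elif rec.alt_allele == genome:
            _swap(rec)
            rec.flip_status = "genome_resolved"
        else:
            rec.flip_status = "unresolved"
    else:
        rec.flip_status = "unresolved"
    return rec


def assign_rsid(rec: QTLRecord, ref: VariantReference) -> QTLRecord:
    """Attach the reference rsID when the harmonized site is in the table.

    Records resolved only through the genome fallback keep their original
    variant identifier and gain no rsID.
    """
    site = ref.lookup(rec.chrom, rec.start, rec.end)
    if site is not None and rec.ref_allele == site.ref and rec.alt_allele in site.alts:
        rec.rsid = site.rsid
    return rec


def annotate_target(rec: QTLRecord, genes: GeneModel) -> QTLRecord:
    """Add gene symbol, strand and signed TSS distance for the target.

    Distance convention: positive when the variant lies downstream of the
    TSS in the gene's direction of transcription (computed from the 1-based
    variant position).  Unknown targets are annotated with the missing
    sentinel and a warning; never an error.
    """
    info = genes.lookup(rec.target_id)
    if info is None:
        logger.warning("target %r not in gene model; annotated as missing",
                       rec.target_id)
        rec.gene_symbol = MISSING
        rec.target_strand = MISSING
        rec.tss_distance = None
        return rec
    symbol, strand, _chrom, tss = info
    rec.gene_symbol = symbol
    rec.target_strand = strand
    pos1 = rec.start + 1
    rec.tss_distance = pos1 - tss if strand == "+" else tss - pos1
    return rec


def compute_fdr(records: list[QTLRecord]) -> list[QTLRecord]:
    """Benjamini–Hochberg adjustment per (target, tissue) group.

    Applies only to records whose input carried no FDR — pre-existing values
    are trusted and pass through unchanged.  Output order is preserved.
    """
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.fdr is None:
            groups.setdefault((rec.target_id, rec.tissue), []).append(i)
    for indices in groups.values():
        pvals = [records[i].pvalue for i in indices]
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for i, q in zip(indices, adjusted):
            records[i].fdr = float(q)
    return records


def split_outputs(records: list[QTLRecord],
                  threshold: float = DEFAULT_FDR_THRESHOLD) -> dict:
    """Partition records into SNP/INDEL full tracks + significant subsets.

    Significance is strict: ``fdr < threshold``.  All four tracks are always
    present (possibly empty), keyed by ``(variant_type, tier)`` with tier in
    {"full", "significant"}.
    """
    tracks = {(vt, tier): [] for vt in ("SNP", "INDEL")
              for tier in ("full", "significant")}
    for rec in records:
        vt = rec.variant_type
        tracks[(vt, "full")].append(rec)
        if rec.fdr is not None and rec.fdr < threshold:
            tracks[(vt, "significant")].append(rec)
    return tracks


def process_qtl_records(mapped_rows, config: FileConfig, reference: VariantReference,
                        genes: GeneModel, default_tissue: str):
    """Run the row-wise QTL stages over mapped rows.

    Returns ``(records, rejects, n_palindromic)``; group-level FDR and
    splitting are separate stages because they need the whole file.
    """
    records, rejects = [], []
    n_palindromic = 0
    for mapped, reject in mapped_rows:
        if reject is not None:
            rejects.append(reject)
            continue
        try:
            rec = parse_qtl_row(mapped, config, default_tissue)
            if is_palindromic(rec):
                n_palindromic += 1
            harmonize_alleles(rec, reference)
            if rec.flip_status == "unresolved":
                raise RowRejected(
                    "unresolved-alleles",
                    f"{rec.chrom}:{rec.start}-{rec.end} {rec.ref_allele}/{rec.alt_allele}",
                )
            assign_rsid(rec, reference)
            annotate_target(rec, genes)
            records.append(rec)
        except RowRejected as exc:
            rejects.append((mapped.lineno, str(exc), MISSING))
    if n_palindromic:
        logger.info("%d strand-ambiguous (palindromic) SNVs resolved by "
                    "position+allele match", n_palindromic)
    return records, rejects, n_palindromic
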